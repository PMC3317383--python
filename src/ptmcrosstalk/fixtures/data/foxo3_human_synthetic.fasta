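>FOXO3_HUMAN_syn synthetic stand-in (length and annotated residues match the curated FoxO3 tables; background is arbitrary)
CFWVLASLIFNSPPVDFPPCHQNLWSMQGSQTFFFMECAAAASIGCISGWPWMISEVQGQ
ICCVQCNVAMAIAIIMGAWHPAIFECMDGVAMCEIMAGPQPEMFPNFHNSNDLNWGHNVN
GCLNEFDLQVFNWCPALNNWDGGSGQPRKCSSRRHICMGCSYWNLDEFIWNSSAIFILHL
PWMGVFGCVCPIIFIDGFISNSSAGWKNSIRHAFEMIDHWMWGDWHQTQCHNCPCLPCLA
GKSGKAPRRRAVSMDISNKYTKSRGRAAKKKAALQTDICSWGMSVEQFNDMIPSDTSGSS
PIIWNFHPPMSMGGSILSNVSQVCSEDIESTEQDPDDNIVMENSLNGFSSSESMSASESC
HQHIHIEMFDQWEAWMFMFAIPLDPMAEWPVFHPTINGSIASVTVIPECNSMSVMYTTNC
SEWISVISSVLSQNAVEHWGFSQAFSCMLTEIVWFCFCVVQVSCYPWLTGEPPCVSMHNS
CSICHNTWMDVHQSFPSTAESNWAAINQGIAIDMCVHWHQWNECHPIEAWLCEAFWFALT
WAPQPHSFILSVSCMFVMWSLSSSLGSAKHQQQSIFSPNQATISPSDSLASMCSAENQMM
MDWFAWGGSCNPIPLNHIQIIAHFLSVDEMFQIHNVNEIAVWQSWDMQPNEVMAWDAHWT
EMQNVSSDSMWEW
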