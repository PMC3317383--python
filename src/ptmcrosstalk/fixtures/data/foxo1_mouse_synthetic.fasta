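>FOXO1_MOUSE_syn synthetic stand-in homolog (shares the methylation-site core with the FoxO3 stand-in)
FFWVLASLIFNSPPIDFPPCHQNLWSMPGSQTFFFMECAAAESIGCISGWPWMISEWQGQ
ICCVQCNVCMAIAIIMGAWHQAIFECMDGVAMLEIMAGPQPEMFCNFHNSNDLNWGHAVN
GCLNEFDLQCFNWCPALNNWDGGSGQPRKCSSRRAICMGCSYWNLDEFFWNSSAIFILHL
PWCGVFGCVCPIIFHDGFISNSSAGWKNSIRHAFEMIDHCMWGDWHQTQCHNCPCLPCLA
GKSGKAPRRRAVSMDISNKYTKSRGRAAKKKAALQTDICSVGMSVEQFNDMIPSITSGSS
PIIWNFHPPMSWGGSILSNVSQVCSEDEESTEQDPDDNIVMMNSLNGFSSSESMSASESC
HIHIHIEMFDQWEDWMFMFAIPLDPLAEWPVFHPTINGSPASVTVIPECNSMSVMYTTCC
SEWISVISSVLSQNAWEHWGFSQAFSCMLTWIVWFCFCVVQVSIYPWLTGEPPCVSMHCS
CSICHNTWMDVHQSHPSTAESNWAAINQGPAIDMCVHWHQWIECHPIEAWLCEDFWFALT
WAPQPHSIILSVSCMFVMWSLSSSLGSAKHQQQSIESPNQATISPSDSLASMCSQENQMM
MDWFAWFGSCNPIPLNHIQAIAHFLSVDEMFQGHNVNEIAVWQSTEMQNVSSDSMWEW
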