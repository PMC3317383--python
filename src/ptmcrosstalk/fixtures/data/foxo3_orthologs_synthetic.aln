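CLUSTAL X (1.81) multiple sequence alignment


FOXO3_HUMAN_syn                     CFWVLASLIFNSPPVDFPPCHQNLWSMQGSQTFFFMECAAAASIGCISGW
NP_001129431_syn                    CFWVLASLIFNSPPVDFPPCHQNLWSMQGSQTFFFMECAAAASIGCISGW
NP_001099865_syn                    CFWVLASLIFNSPPVDFPPCHQNLWSMQGSQTFFFMECAAAASIGCWSGW
NP_062714_syn                       CQWVLASLIFNSPPVDFPPCHQNLWSMQGSQTFFFMECAAAASIGPISGW
XP_615634_syn                       CFWVLASLIFNSPPVDFPHCHQNLWSMQGSQTFFFMECAAAASIGCWSGW

FOXO3_HUMAN_syn                     PWMISEVQGQICCVQCNVAMAIAIIMGAWHPAIFECMDGVAMCEIMAGPQ
NP_001129431_syn                    PWMISEVQGQICCVQCNVAMAAAIIMGAWHPAIFECMDGFAMCEIMAGPQ
NP_001099865_syn                    PWMISEVQGQICCVVCNVAMAIAIIMGAWHPAIFEIMDGVAMCEIMAGPL
NP_062714_syn                       PWMISEVQGVICCVQHVVAMAIAIIMGAWHPAIFECMDGVAMCEIMAGPQ
XP_615634_syn                       PWMISEVQGQICCVWCNVAMAIAIIMGEWHPAIFECMDGLAMCEIMAGPQ

FOXO3_HUMAN_syn                     PEMFPNFHNSNDLNWGHNVNGCLNEFDLQVFNWCPALNNWDGGSGQPRKC
NP_001129431_syn                    PEMWPPFHNSNDLNWGHNVNGCLNEFDLQCFNWCPALNNWDGGSGQPRKC
NP_001099865_syn                    PEMFPNFHNSNDLNWGHNDNGCLNEFDPQVFNWCPALNNWDGGSGQPRKC
NP_062714_syn                       PEMFPNFNNSNDLGWGHNVNECLNEFDLQAFNWCPALNNWDGGSGQPRKC
XP_615634_syn                       PLMFPNFHNSNDLNWGHNVNGCLNEFDLQVFNWCPALNLWDGGSGQPRKC

FOXO3_HUMAN_syn                     SSRRHICMGCSYWNLDEFIWNSSAIFILHLPWMGVFGCVCPIIFIDGFIS
NP_001129431_syn                    SSRRHICMGMSYWNLDEFIWNSSVIFILHPPWMGVFGCVCPIIFIDGFIS
NP_001099865_syn                    SSRRHICMGQSYWNLDEFIWNSSAIFILHLPWMGVFGCVCPIIEIDGFIS
NP_062714_syn                       SSRRHICMGCSYWNLDEFIWNSSAIFILHLPWMGVFGCVCPIIFIDGDIS
XP_615634_syn                       SSRRHICMGCSYWNLDEFIWNSSAINILHLPIMGVFGEVCLIIFIDGFIS

FOXO3_HUMAN_syn                     NSSAGWKNSIRHAFEMIDHWMWGDWHQTQCHNCPCLPCLAGKSGKAPRRR
NP_001129431_syn                    NSSAGWKNSIRHAFEMIDHWMWGDWHQTQCHNCPCLPCLAGKSGKAPRRR
NP_001099865_syn                    NSSAGWKNSIRHAFEMIDHWMWGDWHQTQMHNCPCLECLAGKSGKAPRRR
NP_062714_syn                       NSSAGWKNSIRHAFEMIDHWMWGMWHQTQCHNCPCLPCLAGKSGKAPRRR
XP_615634_syn                       NSSAGWKNSIRHDFEMIDHWMWGDWMQTQCHNCECLPCLAGKSGKAPRRR

FOXO3_HUMAN_syn                     AVSMDISNKYTKSRGRAAKKKAALQTDICSWGMSVEQFNDMIPSDTSGSS
NP_001129431_syn                    AVSMDISNKYTKSRGRAAKKKAALQTDICSWGMSVEQFDDMIPSPTSGSS
NP_001099865_syn                    AVSMDHSNKYTKSRGRAAKKKAALQTDICSWGMSVEQFNDMIPSDTSGSS
NP_062714_syn                       AVSMDISNKYTKSRGRAAKKKAALQTDICSWIMSVEQFNDMIPSDTSGSS
XP_615634_syn                       AVSMDISNKYTKSRGRAAKKKAALQTVICSWGMSVEQFNQMIPSDTSGSS

FOXO3_HUMAN_syn                     PIIWNFHPPMSMGGSILSNVSQVCSEDIESTEQDPDDNIVMENSLNGFSS
NP_001129431_syn                    PGIWNFWPPMSMGGSILSNVSQVCSEDIESTEQDPDDNIVMENSLNGFSS
NP_001099865_syn                    PIIWNFHPPMSMGGSILSNVSQVCSEDIESTEQDPDDNIVMENSLNGFSS
NP_062714_syn                       PIIWNFHPPMSMGGSIWSNVSQVCSEDIESTEQDPDDNIVMENSLNGFSS
XP_615634_syn                       PIIWNFHVPMSMGGSILSNVSQVCSEDIESTEQDPDDNIVMENSLNGFSS

FOXO3_HUMAN_syn                     SESMSASESCHQHIHIEMFDQWEAWMFMFAIPLDPMAEWPVFHPTINGSI
NP_001129431_syn                    SESWSASESCHQHIHIEMFELGEAWMFMFAIPLDPMMEWPVFHPAINGSI
NP_001099865_syn                    SESMSASESCHQHHHIEMFDQWEAWMFMFAIPLDPMAEWPNFHPAINMSI
NP_062714_syn                       SESMSASESCHQHIHIEMFDQWMAWLFMFAIPLDPMAEWPVFHPTINGSI
XP_615634_syn                       SESMSASESCHQHIHIEMFDQWEAWMFMFAIPLDPMAEFPVFHPTINGSI

FOXO3_HUMAN_syn                     ASVTVIPECNSMSVMYTTNCSEWISVISSVLSQNAVEHWGFSQAFSCMLT
NP_001129431_syn                    ASVAVIPECNSMSVMYTANWSEWISVISSVLSQNAVGHWGFSQAFSCMLT
NP_001099865_syn                    ASVAVIPECNSMSLMYTANCSEWISVISSVLSQNAHEHWGESQAFSCMLT
NP_062714_syn                       ASVTVMEECNSMSVMYTTNCSEWISVISSMLSQNAVEHWGLSQAFSCMLT
XP_615634_syn                       ASVTVIPECNSMSVMYTTNCSEWISVISSVLSQNAVEHWGFSQAFSCMLT

FOXO3_HUMAN_syn                     EIVWFCFCVVQVSCYPWLTGEPPCVSMHNSCSICHNTWMDVHQSFPSTAE
NP_001129431_syn                    EIVWFCFCVVQVSCYPLLTGEPPCVSMHNSCSICHNTWMDVHNSFPSTAE
NP_001099865_syn                    NIVWFCFCMVQVSCYPWLTGEPPCVSMHNSCSICHNTWMDVHQSFPSTAE
NP_062714_syn                       EIVWGCFCVVQVSCYPWLTGEPPCVSMHNSCSICHNTWMDVHQSFPSTAE
XP_615634_syn                       EIVWFCFCVVQVSCYPWLTGEPPCVSMHNSCSICANTWMDVHQSFPSTAE

FOXO3_HUMAN_syn                     SNWAAINQGIAIDMCVHWHQWNECHPIEAWLCEAFWFALTWAPQPHSFIL
NP_001129431_syn                    SNWAAINQGIAIDMCVHWHQWNECHPIEAWLCEAFWFALTWAPQPHSFIL
NP_001099865_syn                    SNWAAINQGIAIDMCVHNHQWNEPHPIEAWLCEAFWFALTWAPQPHSFIL
NP_062714_syn                       SNWAAINQGIAIDMCVHGHQWNECHPIEAWLCEAFWFALTWAPQPHSFIL
XP_615634_syn                       SNWAAINQGIAIDMCVHWHQWNECHPIEAWECEAFEFALTWAPQPHSFIL

FOXO3_HUMAN_syn                     SVSCMFVMWSLSSSLGSAKHQQQSIFSPNQATISPSDSLASMCSAENQMM
NP_001129431_syn                    SVSCMFVMWSLSSSLGSAKHQQQSIFSPNQATISPSDSLASMCSAENQMM
NP_001099865_syn                    SVSCMFVMWSLSSSLGSAKHQQQSIFSPNQATISPSDSFASMCSAENQMM
NP_062714_syn                       SVSCMFVMWSLSSSLGSAKHQQQSIFSPNQATISPSDSLASMCSAENQMM
XP_615634_syn                       SVSCMFVMWSLSSSLGSAKHQQQSIFSPNQATISPSDSLASMCSAENQMM

FOXO3_HUMAN_syn                     MDWFAWGGSCNPIPLNHIQIIAHFLSVDEMFQIHNVNEIAVWQSWDMQPN
NP_001129431_syn                    MDWFAWGGSCNWIPLNHIQIIDHALSVDEMFQIHNVNEIAVWQSWDMQCN
NP_001099865_syn                    MDWFAWGGSCNQIPLNHIQIPAHFLSVDEMFQIHNVNEIAVMQSWDMQPN
NP_062714_syn                       MDWFAWGGSCNPIPLNHIQIIAAFLSVDEMFQIHNVNEIWVWQSWDMQPN
XP_615634_syn                       MDWFAWGGSCNLIPLNHIQIIAHFLSVDEMFQIHNVNEIAVWQSWDMQPN

FOXO3_HUMAN_syn                     EVMAWDAHWTEMQNVSSDSMWEW
NP_001129431_syn                    EVMAWDAHWTEMQNVSSDSMWEW
NP_001099865_syn                    EVMAWDAHWTEMQNVSSDSMWEW
NP_062714_syn                       EVMAWWAHWTEDQNVSSDSMWEW
XP_615634_syn                       EVFAWDAHWTEMQEVSSDSMWEI


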