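>U_ex1 lineage=U synthetic=true
FSRQMRYYTTGVIRHVLKEPRTITVGRRWDWQFWRCDSCAASQRKEPEHPWIYQEVPEYW
DGELYKCKAVSQWIPEDLGWLDGYYNQSVAFSHTVQTMYGCDVGNIWRFLWGYHQYAYDG
ADMEALKKERRSWTIAMMASQGTKHKWEAFHIYFASRAYLLKTCVEGLRMYHACGITTLQ
RTDAPKTHMTHWAQVTHEATLRCVWLEFYVAHMTLWWQADGSDYKQWMELVFTSPYGDDI
FQKHNAVYVESTQEQRYTCHVQHEGLYKPLTVRW
>U_ex2 lineage=U synthetic=true
FSRQMYYYTTGVIRHVLKEPRTIAVLRGDDWQFWRCDSCAASQKMEPEKPWIYQEVPEYW
DGEMYKCKAVSQKHREDLGWLDGYYNQSVAFSHMVRTMYGCQVGSVWRFLWGYHQYAYDG
KDQEALKKERRSWTIAMMAAQGTKHKWEAFHWYNALRAYSLGTCVFGLRMYLDKGKTTLQ
RTDAEKTHMTHHAQVTHDATLQCVWLEFYVAHMTLWWQADGSDYFQDMELTFTSPAGDDT
FQKHNAVYVESGQEFRYTCHVQHEGLPKPLTVRW
>U_ex3 lineage=U synthetic=true
FSRQMRYYTTGVIRHVLKEPRTIAVGRGDDWQMWRCDSCAASFRGEPEHPWIYQEVPEYW
DGEMYKCKAVMQFHREDLGWLDEYMNQSVAFSHTVRTMYGCDVGSDWMFLWGYHQYAYDG
KDQQALKKERRSWTIAEMAAYFTKHKWEAFHWYNALRAYLLGTCVEGLRLYLECGKTTLQ
RMDIPKTHMTHHAQVTHEATLRCVWLEFYVAHMTLAWQADGSDYFQDMELVFTSPAGDDT
FQKINAVYVESGKEQRYTCHVQHEGLPKPLTVRW
>Z1_ex1 lineage=Z1 synthetic=true
GSGSFGYFFTSVSRKGRGMGSWIAVSYVDMTQFVLFDGEAAMMYMPTNARWIENEQHEYW
PNEFRKVWAHPQTHNTDNGTLRAYYNQSEAKSHTVCRMYGCDVKPDWGFLRTYHQYAYDG
KDYIALKEDIRSWGAADPAAQTTKHKWTAAMVCFQLRAYLEVTCVWKLRYFCENGKETWR
LIHAPKTHMTQHNVSPCEAILRCAACSFYPAEITEKPQRAGEDRTQDTELVQTRPAGKET
FQFWAAVVVPSLQDQRYTCQLQHQGDAEILTLRW
>Z1_ex2 lineage=Z1 synthetic=true
GSGSFGYFFTSVSRNGRKMVSWIAVSYPDMTQFVKFDSEAAMMYMPTNAEWIEQEQHEYW
PNEFRKVKAHPQTHDFDNGTLRAYYNQSEAKSHTVCRMYGCDVKPDWRFLREYHQYAYDG
KYYIALKEDIRSWGAADPAAITTKHKWTAAMVCFQLDAYLEVTCVKKLRRFCENGKETLR
LIHAPKTHMTQHNVSFCEAILRCAACSFVPAEITLMPQRSGEDRTQDTELVETRPAGDGT
FQFWAAVCVPSGIFQRYTCQLQHGGDPEILTLRW
>Z1_ex3 lineage=Z1 synthetic=true
GSGSFGYFFGSVSRNGCGMVSWIAVYYVDMTQFVKFDSEAAFMYMPTNAEWIEQEQHEYW
PNEFRKVKAHPQTHSTDNGTLRAYYNQSEAKSHTVCRMYGCDVKPDWRFLREYHQYAYDG
KDYIALKEDIRSWGAADPAAQGTKHKWTAAMVCGQLRAYLEVTCVKKLRRFCENGKETWR
LIHAPKTHMTQHNVSPCEASLRCAAVSFYRPEITLMPQRDGHDRTQDTELVETRPAGKGH
FQFWALNVVPSGQFNRYTCQLQHEKDPEILTLRW
>Z2_ex1 lineage=Z2 synthetic=true
GSHQDRYKVQFLQTPGQLEFRIIRAGHAADWQDPRDDSAYASQQIRFWLPFISQDPKAYR
TGETRKKKHHNQTTRVDLGTHRKYELQSNVGKHTVQRQYGCDVKHDASGPVDVHPYKYVG
SKFIMWENMMRDIGAADVGSRLGIPSLEAAFCSEQEVANSETTCVMYSARALMNGQCRKQ
DAGAPTTHMTEHGVSFHTAQKRCWHFHMYLATTTYDWWRDNELQTQWTILNECRPAGDGL
VQVWGIVVVQTGQEGGYPCCVKACGSFEFGTLEV
>Z2_ex2 lineage=Z2 synthetic=true
GTHKMRYFVQFLNTPGMPEFRGIRAGHAADWNDPEDWSAHASQQIEFWAPWISQDPPAYT
TGETRKKKHHMQWTRVDLGTHRKYELQSNVGKHTMQRQYGCDVMHDMSQPRDKHQYKYVG
QKFIMWENMLRDIGAADVGSRLGIPSLEAALCSEQERANLETTCVMYSARALRNGQCTKK
DDGAPTTHMTEHGVSFHTAQKRCYAFSMYLAPTTYDWWRDIELQTQWTALVECRPAGDGL
VQVWGIVVVQTGQEGGYPCGVKACGSFEYETLRV
>Z2_ex3 lineage=Z2 synthetic=true
GSHQMRYFVQFLQTPGQPEVRIIRAGHAADWQDQRDDSEAASQQIEFWAPWIGQDPPAYR
TGETRKKKHHIQTTRVDLGTHRKYELQHNVGKHTVQRHDGCDVKHDMSMPWDKHDYKYVW
QKFIMWEWMLRDIGAADVESELGIPSLEAAFCSEQERANLETTCVMYSARALMNGQFKKQ
DDGAPTTHMDEHGVSFETAQHRCWAFSMYLAPTTYDWWRDIELQTQDTDLVGCRPAGDGL
VQVWGIVVVQTMQEGGYPCCVKACGSFEYETSRV
>Z3_ex1 lineage=Z3 synthetic=true
MSHHMSYCFTNYSRPERNEIRNKIVGHEDDTFNHFFESDMASQRMHCRAGWIEITYPTYW
DGWTEDVSAHHQTGMVDFFTFRGGRNAFRAGSHTVQRMYHCDSGAMMRFLRGEHQYQYFF
KDYIIGKELLRSWACSHPDATKNKHTVERGHVAYAMRMDLPRPCVDERRRSCLRRIITLQ
AMDAAKPWCTQEMALDGEATLDCWATRYRPAEIQQLPIIAGEDQTQDTEYVPAAPAGDGT
RQKDAAANVPSFQEQRYSCGVQWDLLVKPLTLMW
>Z3_ex2 lineage=Z3 synthetic=true
MSHSMSYPFTNEFRLETNEIRNIIVEHEDDTQNHSFESDMASQRNMDRAPWIEITYPTYW
DGVTEDVKAHHQTGMVDFFTFRGGRNAQRAGSHTVQRMYHCDSGAMMMFRRGEHQYCYFS
KIYIIGKETLRSWAASHPDCTKNKHTVERGHVAYAMRMDLQRVCVNERRRSCLRRIITLQ
ADDAAKPWCTKEMALDGEATLDCWATRYRPAEIQQLCIEWGEDQTQDTELVPGAWSGDST
GQKDAAANVPSFQESRYSCGVQWDLLKKPLTLCW
>Z3_ex3 lineage=Z3 synthetic=true
MSHSMSYPFTNVSRPERNEIRNIIVGHEDDTQNHFFESDMASQRMMCRAPCIEYKYPTYV
DGWTEDVKAHHQTGRVDFFTFRGGRNAQRAGPHTQQRMYHCDSGAMPLFLRGEHQYSYGN
KIYIIDKEGLRSWAASHPDATKNKHTVERGHVAYAMYMDLQRPCVEERRRSCLRRIHTLQ
ADDAAKPWCTHEMALWGEATLDCNATRARPAEIQQLCIIDAEDETQDTELVPAAEMGDGT
GQKDAAANVPSFQEQRYSCGVPWDLLKKPLTLMW
>L_ex1 lineage=L synthetic=true
GSLSMRLFFTSVSRPGRVNPTVIAVAIVTGTHACHTDSDAGLIRAEPRGPAVEQACPNVW
DFETQKVWAHSCTRPFCLGIWAGLYNQSEKIFHTVQRMYGCDVGFDGAFSLHYHIYEYRG
KDCIGDHAILCSRTADDYGAQTAKHIFRFAHVYWQLDALLENVCAEKERRVLEFGKETFN
ATDAVLCHMTSMAVSDLEASLECWALSPPPAEGGATWFMDGEDQTEDTELSETYPASDGN
RQKQAAVLIISNLLMRYTCHVLHMPLPAVIILEI
>L_ex2 lineage=L synthetic=true
GSLSMFLFFTSISRPGRVQPLVIAVAIVDGTHAVHFWMDAGLIRAEPRGSRVEQACPEVW
DFETQTVWAHSCTRRFDLGIWAQLNWQSEKGSHTVQRMYGCDVGFDTAFLKQYHIYEYTG
KDYIGDHAILRSRTAQDYGAKTAKHIFEFAHVYWQLDALNENTCVEKERRVLEFGKETFN
PTDAVLCHMTSMAVSDHEASLECWALSFKPAEIGATWFMDGEDQTEDTELVETYPASDGC
FQKWAAVLIISQHLMWYTCHVLHMWLPAVIILEI
>L_ex3 lineage=L synthetic=true
GSLSMRLFFTSFSRPGRVQPLVPAVAIVDGTHAVHFDSDLGLIRAENRGPRVEQACHEVW
KQYTQKVWAHKCTRRIDLGIWVGLYNQSEKGSHTVQEMYGCDVGFDTAFLLHYHIYEYRG
KDYIGDRAALRSRGAQDYGAQTAKHIFEFAHVYWQLDALEKNTCVEEERRVLEFGKETFN
PTDAVLCHMTKMAVSDHEASLECWALSFPPAEIGATWFMDGEDQYEDTQLVETYPASDGN
FQKQAAVLIISQHLMQYTCHVLHMWLPAVIILEI
>S_ex1 lineage=S synthetic=true
FPHSCRSFCTSAERPGRGHPRFVDFGYPSITQFHRFHFDKGLHYMVPCAPWIETEAEQGW
KQCFRKDGAWMQCHRVDLPTLRGNFMQSEAWSHTVQHMYCCAVDSDWRFVRGYAMYHYDC
SNTGALKERLRCWTAWVMYWEGSKHDREAAAVAESANATLGGTCVDGSEREADMGKDTGL
RFDIYKTHSYRHQVAHNESTLRCSHLSFWPAEMGLFGQKNTYDQTQDRELDQTRPAEKGT
EEKWFGFDVRLTMEQRYLCDHYHMGWPEILSPRE
>S_ex2 lineage=S synthetic=true
GSHQCRSFCTSAERPGKGHPRFVDVGNPSVTQFHRFCFDKGAHYMVPCWPWIETEFENGW
TPCFRKVPAWMQCHRVDLVTYRGNSMQSDAWSHTVQTMYCCAVDSDWRFVRGYAMYHGDC
SNTGALKECLRCWTAWVMYWEGSKHDREPCAVAESANATLGATCVDWSEREADMGLETGL
RFDIYKTHSYHHQVAHPESTLRCSHLSFWPAEMGLFGQKDTYDQTQARELDQTRPAEKGT
VEKWFAFVVRLTMEQRYCCDHYHMGWPKILSPRE
>S_ex3 lineage=S synthetic=true
GSHSCPSFCTSAERPGRGHPRFVDVGYPSFTQFHRFHFDVGAHYMVPCAPWIETRFEQGW
TQCFRKVGAWMQCMWVDLRTLRGNAMQSEAWSHTVQHMYCCAVDSDWRFVRGYAMRHYDC
SNTTALKERLRCWTAWVMYWWGSKHDREAAAVAESANATLKHTCVDWSEREADMGTETGL
RFDIYKTHSYHHQVAHNESTLRCSHLSFWPAEMGLFGQKDTYDQTQDRELDQTRDAEKGT
VQKWFAFEVRLTMGQRYPCDHVHMGWPKILSPRE
>P_ex1 lineage=P synthetic=true
GGHLMLGFGTSVSSPNCGEWCAIAYRYYDTTQFMRCGSDSAFQRMWPRMDKEHTFSDEDW
HTDTRQCKMHCIHHRVEKQTCNGQYNISEAGSTMVQRMYGCNVGSDWSFHMGSHQYAGDG
KVIIAVKQDLTSWTAMQAACQAEKCNSEVWHVAMFLRSHASGACMEWHMRTLKNTKKTLQ
STDAPKTAMILHLVSPRETTERCWLLFICSAEITKTEQRDSWDQTQDTEPVGTRCFTYGT
SPKWAAVVVPQVDEQLYTCHTDRENLPKPLHLCN
>P_ex2 lineage=P synthetic=true
GSKLMLGFVTSVSSPNCGEIQFIAYDYYDTTQFMRCGSDSAFQRMWRLMDKPHTTSDEDW
HTDTRQCKMHCIDHRVDKQTCNGQYNISWAGSTMVQRMYGCNVGSDWSIHMGSHQYAQDG
KVKIAVAQDLTSWTAMQAACFAEKINSEVWHVAMFLRAHAEGTCHEWHNRTLKNGKKTLQ
STDAPKQMMILHLVTDRETTERCWLLFICSAEITATEQRDSWDQTQDTEPVGTFCFTYGT
SPKWAAVVVPQVDEQLYTCHTDRENLPKPKHFCW
>P_ex3 lineage=P synthetic=true
GSHLMLGFVTSVSSPNCGEWCFIAYRYYDTTQFMTCGSDSAFQRMWPRMDKEHTFSDEDW
HTDTRQCKMHCIDHRVDKQTCNGQYNISEAGSTMVQRMYGCNVGSDWSFHMGSHQYAQDG
KVKIAVKQDLTSWTAMQAACQHERINSEVWHVAMFLRAHAEGTCVEVHMRTLKNGKKTDQ
STDAGKTMMELHLVSPRETTERCWLLFICSAEITETEQRDSWDQTQDTEPVGTRCFTYGT
SPAWAMVVVPQVDEQLYTCHTTRENLPKPWHLCW
>OUT_ex1 lineage=OUT synthetic=true
GSHSMLYQQTSVSRPGRGPEKFDAVGYVQDTQFVRFYVKAASQGMEKRAPFIEQEGAEYT
DGETRIVKAHSQDHRVDLQTLRNYYNQSEAGDHMTQRMYGCDVYSKWRFFRNYSQYAYVG
KDYWALKDDLLSNVAKDMAAQTTKHKWEAAHVAEQLRAYNEGTCKEWLRRYLWNGKEHLQ
RTDAPKTHMAMHAGSDHEFTLRCWALSFYPAEITLTVQRYGEDQTSDTELVETRPAGDGT
FQKAAAGVVPSGQECRETCHKQHEGLPKPLTLRF
>OUT_ex2 lineage=OUT synthetic=true
RSHSMLYFQTSGSRPGRGFEKFDAVGYVHDTQHVRFDLKAASQRMEKRAPLIEQEGPEYW
DGNTRKVKAHFQDHRVDLQTLRGYYNQSEAGSHMVQRMYTCDVYSKWRFFRNYNQIAYVP
KDYWALMQDLRFIVAKDMAAVTTKHKWEGAHVAEQLRAYLEWTCKEWLRRYLWNGKEHLQ
WTDAPKTHTAMHAGSDHEFPLRCVALSFYPAEITLTVQRYGEDQTSDTELVETRPAGDGT
FQTAAAGVVPSIQECYNTCHKQHEGLPICLTLRF
>OUT_ex3 lineage=OUT synthetic=true
PSHSMLYFQTSVSRPGRGFEKFDAQGYVWDTQFVRFDVKPASQRDEKRAPLIEQEGPEYW
VGETRVVKAHSQDHRVDLYTLRGYYNQSEAGSSMVKRMYGCDMYSKWRFMENYEQYAYVG
NDYWALKEDLASIVAKDMAAQTTYHKWEAAHVAEQLRAYLEGTCKEWLRRYLFNGKEHLQ
RTDAPKTHMAMHAGSDHFFTLRCWANSFYPAEITLTVQRYMEDQTHDTMLVETRPAGDGT
FQKAAAVVMPSGQECRNTCHKQHEGLPKPLTLRF
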