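>A1_I_ex1 lineage=I synthetic=true
GSHSMRYFFMSVCFPGHLEVKFIAVGYGDDTQFPRFDSHAAFQLCEPRAPWWELEPPEYR
RGRGREVQAHSQMINVDLRTLMAYYNQSEA
>A1_I_ex2 lineage=I synthetic=true
GSHSMRYFFMSVCFPGHFEVKFIAVGYGDDTQAPRFDSHAAFQLCEPRAPWWEIEPPEYR
RGRGREVDAHHQMILHDLRTLMAYYNQSEA
>A1_I_ex3 lineage=I synthetic=true
GSHSMRYFFMSVCFPGHGFVKFIAVGYGDDTQFPRFDSHAAFQLCEPRAPWWEIEPPEYR
RLRGREVDAHSQMINVDLRTLMAYYNQSEA
>A1_II_ex1 lineage=II synthetic=true
GSHIMEYKFPSVSRPGFVEHRFIAVCAVGATNFVRFDAGDATAHMEPIAIWIECWGPEYK
DYSRRKVKPHSFTRRVDLGCLRGYDNQSEF
>A1_II_ex2 lineage=II synthetic=true
GSHIMRYKFPSVSRPGFGEHRFIAQCAVGATNFVRFDSGDASAHMEPITIWINQWGNEYK
DYSRRKVKPHSQTRRVDLGCLRGYDNQSEF
>A1_II_ex3 lineage=II synthetic=true
GSHIMRYKFPSVSRPGFGEIRFIAVCAVGATNIVRFDSGDASAHMEPIAIWIEQWGPEYK
DYSRRKVKPHLQTARVDLGCLRGYDNQSEF
>A1_III_ex1 lineage=III synthetic=true
VSGFMGYKGTFVDRPNRFNPRFIAVGIVDHTPFVRFDSDKASWRMEPNAFRIIQEEDEYK
WGETTSVKDHNQSHRADGGCEMGYSNQSYI
>A1_III_ex2 lineage=III synthetic=true
GSGFMGYFGTFVDRPNRFNPRFIQVGIVWHTPFVRFWSDKASWRMENNAPRIIQEEDEYK
WGETTSVKDHNQSHRADGGCEMGYSNQSSI
>A1_III_ex3 lineage=III synthetic=true
GSGFMGYFGTFVDRPNRFNPRFIAVGIVDHTPFVLFDSDKASWRMEPNAPRIHQEEDEYK
WGETTSVKDHNQSHRADGGCEMGYSNQSSI
>A1_IV_ex1 lineage=IV synthetic=true
GFHFMDYFFNSVSPRGCYEPSSISVWYYDDTQFVRFGMDWASQQMSTRAPWIERYGIRYS
AGGTYNVIAHSQTTKVDCKVMAGYNNQSEN
>A1_IV_ex2 lineage=IV synthetic=true
GFHFMDYFFNSVSPRGHYEPSFISVGYYDDTQFVRFGMDWASQQMSTRAPWVERYGIEYS
AGGTYNVVAHSQTTKVDCKVMAGYNNQSEA
>A1_IV_ex3 lineage=IV synthetic=true
GFHFMTYFFNSVIPRGCYEPSFISVGYYDDTQFVRFGMDWASQQMSTRAPWIERYGIEYS
AGGVYNVVAHSQTTKVDCKVMKGYNNQSTA
>A1_V_ex1 lineage=V synthetic=true
GKHSFRYFWLSCSRPNLCENYFICTGYERDTSKVRFDSDAASSRDEYFAPWWFHYGTEYK
AGEWRKVKAHYQFFRCILGCLRCYYNQSEA
>A1_V_ex2 lineage=V synthetic=true
GKHSFRYCWLSRSRPNRCENYFICTGYERDTSFVRFDSDAASSRDEPKAPWIFHYGTEYK
AGEWRKVKAHYKKFRCILGTLRCYYNQSEA
>A1_V_ex3 lineage=V synthetic=true
GKHSFRYFWLSRSRPNRCENYFICTGYERATSTVRFDSDAASSRDEPKAPWIFHYGTEYK
AGEWRKVKAHYQHFRCILGTLRCYYNQSEA
>A1_VI_ex1 lineage=VI synthetic=true
GSNSMRYFKTSVMIPGRGERRIQAVGPTDHDQFVRFDSDQSSQRYEQRWPAYGQETPEYH
WGFKRKVAQFKQMHRGWLGCRRGYYNQSEA
>A1_VI_ex2 lineage=VI synthetic=true
GSNSMRYFKTSVMIPGRGERAIQAVGPTDHDQFVRFDSDASSQRYECRWPRYGQHTPEYH
WGFKTKVAQFDQMHRGWLGCERGYYNQSEA
>A1_VI_ex3 lineage=VI synthetic=true
GSNSMRYFCTSAMIPGRGERRIQAVGPTDSDQFVRFDSDACSQRYEQRWPAYGQEIPEYH
WGFHRKVAQFKQMHRGWLGCRRGYYNQSEA
>A1_VII_ex1 lineage=VII synthetic=true
GPHSMWYSFISVSRPGRKVPRFYAVGYASDKQFVPFDSDAAVQRMNNGTPWIEQPGPEYT
DRETRKVVAVWPLHYVDLGTLFGYQNQSDA
>A1_VII_ex2 lineage=VII synthetic=true
GPHSMWYSFISVSRPGRETPRFNAVHYADRKQFVPFDSDAAVQRMNNGTPWIEQPGPEYT
DRETRKVVAVWPLHSVDLGTLFGYQNQSDA
>A1_VII_ex3 lineage=VII synthetic=true
GPHSMIYSFISVSRPGRKTPRFNAVGYADDKQFVPFTSDAAVQIMNNGLYWIEQPGPEYT
DRETRKVVAVWPLHYVDLGFLFGYQNQSDA
>A1_VIII_ex1 lineage=VIII synthetic=true
GSDAMRYFFKEQSNVGRGSPAFKAVGYVLDTQFCRFDQDAASQKHECPIPWMEQMNPDYW
TWETAKVKAEIQTSAVELQCLRNYNNQSFA
>A1_VIII_ex2 lineage=VIII synthetic=true
GSDAMRYFFKEQSIVGRGSPDFKAMGYVLDTQMCRFDQDAASQKHECVAPWMEQMNPDYW
TWETAKVKAEIQTCAVCLQCLRNYNNQSFA
>A1_VIII_ex3 lineage=VIII synthetic=true
GSDAMRYFFKEQSNVGRGSPDFKAVGYVLDTQFCRFDQDAASQKHECPAPWMEQHNPDYW
TWETAKVKAEIQTVAVELQCLRRYNNQSFA
>A1_IX_ex1 lineage=IX synthetic=true
HAPSMVYDGTSQSRPGEEKIDFLAVIYFDCTLFLRFMSDINSQRDPPHATWIEQHGAEYL
DGETEFVKAHSQTHWVDLTTLQRYYNQSDL
>A1_IX_ex2 lineage=IX synthetic=true
HAPSMVYDFTSQSRPGNEKIDFEAVEYNDCTLFLRFMSDANSQWDPPHATWIEAHGKEYG
DGETEFVKAHSQTHWNDLTTLQRYYNQSEL
>A1_IX_ex3 lineage=IX synthetic=true
HAPSMVYDFTPQSRPGEEKIDDEAVEYNDCTLFLRFMSDANSQRDPPHATWIECHGKEYG
DGETEFVKDHCATHDVDLTTLQRYYNQSEL
>A1_OUT_ex1 lineage=OUT synthetic=true
GSHSMRYFFWSVSRPGGGEPRFIAVGEVDDTQFVRFDYDAAMQRMEPRSPWIEQEGPCYW
DGESRKVKAHSQTKRVDYGTLRGYYNQSEA
>A1_OUT_ex2 lineage=OUT synthetic=true
GSSKMRYFFTGVSRPDRGEPRFIAVGWVSDKQFVRFDSDAASQRMNPRAPWNEQEGPEYW
DGETRKVVWHSQTHEVDLGTLRGYANQSEC
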