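>HBB_HUMAN Hemoglobin subunit beta (synthetic stand-in) GN=HBB OS=Homo sapiens ROLE=marker
MSHGQTEAVVALKEGPTYIKLCGSDKECQDSNFDYLMMKTPSSSSCYIARFHYIIYCPME
EERLPMWDVAQERMSTEQWTMGKENAQGQNEEHRSFHTWGDMRSCDNDLKFLWEFHNELD
CMRYGPQHHQAIKVFFILMKCWNFHQ
>HBB_BOVIN Hemoglobin subunit beta (synthetic stand-in) GN=HBB OS=Bos taurus ROLE=marker
MSDGQTEALVALKEGPTHIKLCGSDKECQDHNGDMLMMKTPSSSSCWIARFHYIIYCPME
EERLPMWDVAQVRMSTEQWTQGKEQAQGQNEAHRSFHIWGDMRSCDNDCKFLWEFANELD
CYRYGPQHWGAIKVFFILMKCWNWHQ
>HBB_CANFA Hemoglobin subunit beta (synthetic stand-in) GN=HBB OS=Canis familiaris ROLE=marker
MSHGQTEAVYALKEGPTYTKLMGSDKECQDSNFDYMMLKTPSSSSHYIFRFHYIIYCPME
EERLPHWDQAQERMSMEQWTMGKENAQGQNEEHRSFHTWMDMRSCDNDLKFLWECHNELD
IMRYGPQHTQAIKIFFILMKCWNFHQ
>HBA_HUMAN Hemoglobin subunit alpha (synthetic stand-in) GN=HBA1 OS=Homo sapiens ROLE=marker
MYMHEIHKVMHCDFWTWHKHFVWPNRLFMEMQVIVKSVHNMLAVFNHARMSTLFPAHMSQ
AKYSNYGQMLKYACAQYVKALSEQDPRTTSHAEFEFIYWRWCPWQVTCKHMNNSWQSRTN
PQWSMKWEFEACGVEHRSMNP
>HBA_BOVIN Hemoglobin subunit alpha (synthetic stand-in) GN=HBA OS=Bos taurus ROLE=marker
MYMHEIHKVMHCAFWTWHKHFVVPCRLFYEMQVIVKSVNNMLAVFNHARMSTLFPAHMSQ
AKYSFYGQMLKYACAQYVKALSEQDPRTTSHAEFEFIYWRWQPWQVTCKHYNNSTQTRTY
PQWQMKWEFEACGVEHRSTNP
>HBA_CANFA Hemoglobin subunit alpha (synthetic stand-in) GN=HBA OS=Canis familiaris ROLE=marker
MYMHDIHKVMHCDFWTWNKVFVWPQRSFMEMQVIVKSVHNMTAVFNHARMSTLLPAHMSQ
VKYSNYGQMLKHAVAQYVKALSEQDPRTTSHAEFEFAYWRWCPGQVHCKHMQASWAGRTN
PQWSMKWEWEAYGVENRSMNP
>SEMG1_HUMAN Semenogelin-1 (synthetic stand-in) GN=SEMG1 OS=Homo sapiens ROLE=marker
MWNNFSWMILTSRGTWQYEINRCCNNCPTTFDGIKNWEMGCDCKSYIHWTLMFDRVISFG
NETMKAAMVLWGAAACKQCPIWSMCLDMRWANTVGGLRAQWFDRSMHGNKEYFFMCMSRL
NEYAVLEMKDPGCGLKQGMANPCRIFSNSKWAIQANDWHQKSVTCGYPTTRMTMETSSKI
FCEPHCYTTHEKHLDFFAPRNSWQVIRFNCPCADVVKQLACTTHNWKEDPNVPFTVLAKL
WCDGEFVRMQCEARLICHCSHCKIVLWAQPPHHDPKLFPAGPAFKQGLHTGFIHGCKMST
>SEMG2_HUMAN Semenogelin-2 (synthetic stand-in) GN=SEMG2 OS=Homo sapiens ROLE=marker
MDYWHHKQYFNQPYDMLWKDHDWVGVNPKHFLCEKNWIACVKTDIWPWAWEAKMHHCMLY
RENGSWVQDIGPRTSWVNYCHWRYTQSGTMCHAAERDVNMTSSCQIRFQTWSCPPFLTGK
LGYWGMMWLHCIKVAVEMICDPKCSEMPVTNYMIEKDMYPLCWYKDHHEGTKDTDWFKAM
VWSTFHYYMQRMLEMYTYEPSKAIFTHPNERANCEQREWIFCSDLWAAKHPDFSKFQIHH
LLCKAGYESFSARVFQLCGWITYRGPAGYVISKCVFMPGEVWCKVTWGMSYKSLPSWDRI
SMQHGDAEVARGQSENVFHA
>PAP_HUMAN Prostatic acid phosphatase (synthetic stand-in) GN=ACPP OS=Homo sapiens ROLE=marker
MVDHQAQRLFSGQLKNGQANGCNHEFKMMEYWVQIYDRQGWFEKGPPPHIWQHGVGRGSN
ACDGKCPCLAIGQMHRVSLFWCCQDDPWKMSQQVLMHGCKAAIGVWKLEDNFKAFIYTVT
IKQSDSITRWFQSNRSQYNHPEMKMMGNEYTMHKTNWTFLRFWPGCWRQYAHQKEGDNEY
DTQRYLETLRGEFDMNSKDWFMSTLYLRNAVLTCRAYSIELINNWRGVILPWFQDGGFRE
NEHARGWTDY
>PSA_HUMAN Prostate-specific antigen (synthetic stand-in) GN=KLK3 OS=Homo sapiens ROLE=marker
MDGSLTDGVPEKWFFHTPIHPQANKNEGENSNARAYVMVSQICWHKHCQNYCIDTRFYQA
YKIWMIGSHILANGRLVMVEVMHMGVSKCQTMQGIRGDFIGRFNHHMTSEWKVCSPFQYK
IGAFGSPGEGRSPPYWKLVTEGYYTRMSWAEGEARGQCISWMVVRTFFEEAQIGQKWLWH
IDLAPGKTLEDAYKWFWCHLRGGQIIYVSSEDRAFSTVRVDSSTKANIFT
>CORNU_HUMAN Cornulin (synthetic stand-in) GN=CRNN OS=Homo sapiens ROLE=marker
MADPFMHMSEIHRGMNTQLDISIAPKMSEVNTYDNRTAGNFFTVMAWRVMYALAQGHIYK
MQDHMKWYPVWQMLFQRWPDEMKNNLDQEYEREWHLWYQVFIYRFNNLHLCNAQTAKVEG
ETVECGVQFKADIMNLKNHGCALQCDFEKDGCVHLMAKFSIDPHMYNHKGVTDQEHRHDD
LHAHGMNIKLMDQLGKHDPVVIPMERYGTVNPTSLYRYDVIGYEGKAMAISHGQANAWRY
QDADADRQAVGATQHSWYRATACFPVQEKAHWEFICYPIRAAFAWPSGIKSVEPDWKCQD
>SPR1A_HUMAN Cornifin-A (synthetic stand-in) GN=SPRR1A OS=Homo sapiens ROLE=marker
MYLNNGPVKFVEIFNPRFVGNSRQTDLINGIMLQKWPEINMRGCNMYCYEKACIPARMWH
TGLTPWWGRFMQAVPESTWGDKFYEPGPSV
>SPR1B_HUMAN Cornifin-B (synthetic stand-in) GN=SPRR1B OS=Homo sapiens ROLE=marker
MYLNNGPVKFVEIFNPRDVGNSRQTDLANGIMLQKWPDINMRGCNMYCYEKACIPARMWH
TGLLPWWGRFMQLVPESTWGDKFYEPGPSV
>INVO_HUMAN Involucrin (synthetic stand-in) GN=IVL OS=Homo sapiens ROLE=marker
MTECGVHMPDYYLRDGNYSYQSYQIIKIFEYMQEKVYAINSKGFSMDMKGDPCECMLKFF
HFTSDLIKEQDETNKDTFVHDKDVSGNCYRNVDNTLQPVLRDCLEGCPFHRDSYQHISMF
KDSDIPCVHVKSACQGKHENIMFPSNGKCQMSVATPHHTRGINQCMIRMMYEHHARCCGD
>AMY1_HUMAN Alpha-amylase 1 (synthetic stand-in) GN=AMY1A OS=Homo sapiens ROLE=marker
MNIHSTIMWEKNCFLHGIKIHEWPMMWDFGRHVVHCIEANVNYKFLQCCHEFNSREADCM
NTQEERFNCWLWNMNFNKGQMFTITMGWMLKHLQCWDANKYPQDSMSNRQFMWQMNRCVY
TSYWPKGVIIHELRVASTMKIQQDMACIIIFHRSCLVGCEQVNNRMNYYYVNRWHVHDMV
ETEDRYTYAFCICKHHFIGLFTWQKDHQGHNGCMNRFWNNEKCCANYRGTACWYTYIRNV
VHPTTNGILKYVMFPRENGMDDGFVAGYKEIIEFTHLRVW
>AMY2_HUMAN Alpha-amylase 2 (synthetic stand-in) GN=AMY2A OS=Homo sapiens ROLE=marker
MNIHSTIMWEKYCFLHGIKIHEWPLMWDFGRHVVHCIAANVNYKFLQCCHEFNGREADCM
NAHEERFSHWVWQMNFNKGQMFTITMGWMLKHLQCGDANKYPQDSGSNRQFMWDMNRCVY
GSYWPKGVIIHELRVLSTMKIQQDMACIIIFHRSCLVGCEQVNNRMNIYYVWRWHVHDMV
ETEDRYTYAFCICKHHFIGLFLWQKDHQMHNGCMNRFWNNEKCCANYRNAACWGMYIRNV
VHPTINGISKYVMDPRWNGMDDGFVAGYKEIIEGTCLRVW
>PLUNC_HUMAN Palate lung and nasal epithelium protein (synthetic stand-in) GN=BPIFA1 OS=Homo sapiens ROLE=marker
MVNITDCSDMMQRALGNMYMPCSQKETWANIGPDPTPRMDCIVRTWQAYQMAMAKNDWDT
QRGLLIPIIKDMFAEMQRWEFMDMYLTLRTSPESRWMSSVVKCVSQNADVKVVGLLYPEF
ARMWFPVTWGIGEYKWCTNEKFFCIVERIQPSDIIPGFPKDWAIEYLAWRVQDAMTKYMP
>ALBU_HUMAN Serum albumin (synthetic stand-in) GN=ALB OS=Homo sapiens ROLE=marker
MGTEMGFVNYPLKQHMPFVGTRCMTDLESSEASRCGLGMPVDNKFYCEEHIEHRLGPVEI
NPIKHDFLYPWRCMTPFIKASDSPWKDSHDIPKGIEQQRVPECENKIANHHVIRVSVEML
ARGMFQPKVYHSGRMVLEMGMFITHQRCYPLMPMGCGMRCHLEITFRVFVAHRYHGALKF
GIWCMDFNTKYSQVMSHCGYCKVNYCIKGLFWEFMPRTEHWNELEHDDKGMTAVRCESFE
SSTRQDNESTYRIYLHSFVHNNGKYIWHTQNTMGKVEIVFKMSEHIFAYPIRMVLGSAGD
>IGJ_HUMAN Immunoglobulin J chain (synthetic stand-in) GN=JCHAIN OS=Homo sapiens ROLE=marker
MYLNHCNKYGLVMAACAGIPKEPNQGKIGLWVVFGKCSMCFRVASNDNMTRVGSPSGWGD
HRCQGFYGIGHMFKGYSVVRHDEPWFRYLTNGLGNKFNQCFEPTRACCCHTEEPRSMWIW
VVESIRLVHWISRMQIACCM
>IGKC_HUMAN Immunoglobulin kappa constant (synthetic stand-in) GN=IGKC OS=Homo sapiens ROLE=marker
MQMDWNKNPCLWNCTFEKHSWHDQDMIFYKHWSDFVWKWMTMQDQIMYKWTSIFGDLRMM
LPSVQYLQWRHLYHLHVPMSAVRECSYFKSAQCVEPSPCRGNYHWV
>IGHA_HUMAN Immunoglobulin heavy constant alpha (synthetic stand-in) GN=IGHA1 OS=Homo sapiens ROLE=marker
MIIHNVRVAWISPFANRSYLNTYQFLDKQIPNSRMADWENIMDDFQRVWGLCSWTEERYS
VVHDVCEAEKVQIMARDISFEEGDVPRTFQEDMQTNPNRADSENSCWFQKNWECLMHHRD
LYIPPEDFIKNWGHCWIKLFWAVANTYDKHVGSGRVQDYE
>UROM_HUMAN Uromodulin (synthetic stand-in) GN=UMOD OS=Homo sapiens ROLE=marker
MTCDFDCLYGRTFVSYKAVQLMCNFKMTTPVARLSGNSEWIGGGPKDTATPYTFGERVTD
CPLRCHSSYFYLFQCRAGDILIDYPHTCKNPIAALALVLHERAAQNWGKIILVAGAPYMS
RMDELTKYSCINWGFEELWRWMVTWLCKYGNYYWKNNVQTPPAQMRAGQEDPQWCRVCMC
FWKSFIVMWYSRLTCVLIPLCVKHNMQHERWDTGVCKMETGGMHMYRCWHDFMKMLSYQE
MSHKWNEFVDPQDDTKVATNIRCGVCTSHQFSLQKMTEMEYRCITSFKIDFENHRNGVPP
>AMBP_HUMAN Protein AMBP (synthetic stand-in) GN=AMBP OS=Homo sapiens ROLE=marker
MNMIVHSLDRMEAAEQDERSEENTLCGFFRDLQTCDFEKWIAYACHLRAMGYINQWLKSI
YCQNEERFIGEPGPQQVDGKALSSMTLRQIHLCDPGLSNKCFQAVPFIEVRMWQWTECKH
YEFVTCRQFQGDPMWVKVANMEFYEWFYNRIMSNILSVQFYGRTVEDVWEHAMQQKLHGD
GCNPQHHWKEGHCDETKWPW
>K2C1_HUMAN Keratin type II cytoskeletal 1 (synthetic stand-in) GN=KRT1 OS=Homo sapiens ROLE=contaminant
MHMQFEQYKTFNQCMHRMFIWYCKVMHLCPKGYNVVMVPNKMQVQWRLCFHAICIYGKDQ
QYSLRTGEDPRELIDQRECHGITRYACSPLGIMMRECQYHWYMDHKENTPTRVVLMIFTM
ECYKQCLMFRSITLTPDKCHGDYKTEQETPLNMWRSGDFVLTALEIKWNHYHMDYDDYCR
EIFVARQGVCVSIEWQRIQFHTLAIWHANRMAMCQLERAAAEIKGDHFYSYASKDNVVSF
CVPKLDTLQG
>K1C10_HUMAN Keratin type I cytoskeletal 10 (synthetic stand-in) GN=KRT10 OS=Homo sapiens ROLE=contaminant
MHPHHSCYMSALNKNSVHVIPILQRVCTHVPFWPYKIEQCQKAITGQKVAQYLSHMCHKY
IHWSWYKHILVAECSDPLDKQLSETPDRQMHVVVQMDVRHPYENCKVWQGGMMLVKFMIC
YGRLWAISYYTICGVRVSMTSIGPFQHHKVYFVPCKHTLICVLQDMNKASIATNFIRNPI
YYQGSEQHRLGFWQNKETSGPLCYYRCCNNIMVWRTPQFDRLVLAYKNPFTQKFMQVTGV
FKFFYDYWWT
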