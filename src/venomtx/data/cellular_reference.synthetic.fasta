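>CEL01 synthetic actin-like housekeeping-style protein
MIGGLEREQLLTLNMAGWDLDRMGVPNTQVAGNTPFPIGSAPRVVVFAAIWDAFGLDTQT
INVLEQSERVKYTIDALYEILDMSNVESIVESYTSANFGKWLIDQTDLKETVRGNRNTMS
GIKGVVPGAHKREKEILRLAGNPHSVQSIKEDLSEKPQDDWSSAWEDAEIFSEANAAHHH
ILLFNVIAARLNKKQAIVITGRADI
>CEL02 synthetic tubulin-like housekeeping-style protein
MASKIGHNDEYLSEALTFYLINSGITGSYPMIDLHIASAQENHHQVDYYVRTEIKSLGLE
HTHMFQYEFLEIILESGDNLELVEMKMEVDESEAISWETGRSADIHYSQQVSKNLDALAE
RKAVLRVDEQIGGPVGANGPAETSPNFLIGKELALRNLERLARSEHRRTRTPANFYTLLA
FFLAMMFEGTLSSHVSVMLSGESLKSSKNRFLGLMAIKRLKSQHSGPPRSVMEEVIIALV
VQVWRPHQFADHL
>CEL03 synthetic ef1a-like housekeeping-style protein
MQSLDTPDFIHHIPGAPRAHSRASVLKQSEGFLNDGAREKRANVMMGAKVLLNLESKSLM
EEVPNEGIRSPETLHGLFIYLVALKGKFYKITISKHPRIMLHQVQNPARKSMTSKKGVLA
PVALAGGRHEDETLRADAEQRDHNGVSDLILGFETIEDSLLATPHGEFVLTHEELDVYRI
SIRMQEGDQPFQDGEIILVA
>CEL04 synthetic gapdh-like housekeeping-style protein
MTIEDSIMKGPLLVGPDWPKENGVRPGRSWIHQFSGYRPTGRKVGKLSSDAGNALQDIEY
LSNFERSAPRLAYTIKHTNLDLVITYGKETVKSGGLTTFPIIFSINIREVPENSAVLLEH
KRGNNRIAALARRYVKRHSFSDNGRQIELFASGLVVWDHPLAGPFYDQVLELVDSPLHIP
VRDYNVNQLHLAFNDSQELSLDVVLKS
>CEL05 synthetic rps3-like housekeeping-style protein
MLYKEPRHEEHISIDTQLFSIVIVRPVDGQEFPNYLEVADQIGLSTLMSNKAAGIDTTHY
DAEVAAPFPAQTKTSWNAHYFIYYLIKSAFSVWRSQENTRQLRLSILKDKEGEEIRINSI
EASQLTMLKIISATGRQGPAIHDLSTIKSRLLEAKRTAAAILQLHPKSGNARHIYYLGKF
IMDQKLEGRHNRSIPIIMPIGKTRSGYRATLVRVGRTVPEYKALATTTRLAATRQK
>CEL06 synthetic hsp70-like housekeeping-style protein
MGMAFLTIAFISFNIGTKIMKTPENTKPEPPAEFAIASRIYETVKGENLPGGSMRNILQG
TNDYLEGDLIKLLMRKDYVSATKGIRVAVAVGVLKRPYELFTGDALRNVVIAVSTFLFNQ
GSIAALTLSQKIRSEIPEEFGKKTTGDLFANFSLVEINPFGKDDNLEQLPPPQAAETMYV
RWIEVDRRAGQDGRAQSKNGFSSLPAASDTFQAYDQFIFASLLGHVDSKTLSVHDSTLIV
GGFELKLMSQIQR
>CEL07 synthetic atp-synthase-like housekeeping-style protein
MGRHSGERGEAGLKPVRVEPLLAKRGQTYTREEAPWQLDLIGAVYDFVHIKLALIGFKEV
GPDNLTTSVLSFAEEVGMKSNIQIRINWIDDFGRAQRNGVSTFRRLSLEMFAVNNLQLRQ
RQPLAMITNDEQQIALVDRPSGTELMGAHVLQIADQNEDAYFMIFLRSLVQYLELPLSNV
RGLMRDPPWWIVKTLNVGHDDSRTLSNT
>CEL08 synthetic enolase-like housekeeping-style protein
MAQILYVEVEVEGELEEGRYGEKKPLLIRIDDEKSMPLIITKYTIERFHTQLQDSPIAWV
GRFDPSFLAAIGLIVTPPIKLVSLQVEIMWPYIIEQVTNPPMVTGVTQNNIRQQVALDRL
HIMVRFQAPHAEKNDARKPLYFLPEPWQYYKLRAIIIPSFNKTERRPPALVGPPPMLNPP
DELDDVTRATAQEKGKLQAT
>CEL09 synthetic histone-like housekeeping-style protein
MIEYITSRQRFKYILNQLRSGAAADANAARSRIRFAQSDVWANTEDKAVYVDLAFMQNSS
FSSVQSYQALGDGEIGKEAQHGLKHMGRYPLVLIEKIAQVLDMGSLNKPYADTTQDALYI
DQNEYVLLLAQLKRLRTAHANFFTQPLIMFINKPFLVIKPGEQKNVTERRSQRSRHQKAN
TSASRDILSSSLTVQLFKHLLRRAKTADLFLQ
>CEL10 synthetic ferritin-like housekeeping-style protein
MTQNAIRPRLRNMILSAMAGWFQDRAATKIGMMGPWILGSWTELQLIPAAAEGWEDMTRF
ADDLTFAINASGFAATISDDKAAVSIREPDGKNDSRDLVSAYRLFAGTARGVLIPLVTRF
ELRSTIITKDERMWKARGHEHKTLEGVFLYVNDFTRAMAFLVGFFKKRVIIISFLQIEVG
NIVRVESEQRW
>CEL11 synthetic cathepsin-like housekeeping-style protein
MNNHLDFGSVMLENTMDLDSLLYYHEMAHVKSALIQNKPKGASNEGVRVAQVHASATRKI
DGSVSVTVERKGREREVQKGDGPADDDRPIIEEFRERGSTSMSDGTRSTSGDPRGSLDLR
KDMAVVPQDTPLFLARLPQMLLRQAPFIPLQRFLVIQDFLPMRQASREDGHGNYIRYSIQ
RTLWLLIRTSRDTEAVKEQHRGPLLKHNGLFLANDLLVFDNSLTLNEYVL
>CEL12 synthetic lectin-like-noncys housekeeping-style protein
METNPPVETVDVHERDANVDGVLDSPVLAYSRPLERGAAAIEHQMDRDEVVHDTIATSVF
NTFGIGLSQIQPHTRNGDVKVALVSYFTLLLQVHQFIRASIDVERVASKILAVVAKKPQW
LEAKHAMQAIDLLMAATPTYLLLSDVDQQQAESEEFVVGSLLYQSWGNQNNPLTLGPPGA
VEDDAKEQPDVVTYIHREDTATFFVDLSIGHDKEKLFALPAQPDAI
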