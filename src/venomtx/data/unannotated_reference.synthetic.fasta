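>UNK01 synthetic hypothetical-1 protein of unknown function
MEAFTQIATIGLFLDTYISFALINSALTLESAKTHGMHWLVTDYFRKRADIKRLFILIQL
PRSDGVAQEEFYLETADPYEDTLLKFWFALFATVSPPFVGIEFRLPESAGTNPVAAEPTT
LYKIVLFLNNKGVRDA
>UNK02 synthetic hypothetical-2 protein of unknown function
MIKRSENLTPLELRTTATSELFGVEPDFTTEDTSDIAYIFIHRNGSWMTEVLLFAAHWYQ
HDEYTERGETYENSWPTGERPLEANTVEYYKKLLVGGIEYTAKRKASLSPMDKKLKNKQK
HFFVGGPAQVFDI
>UNK03 synthetic hypothetical-3 protein of unknown function
MHIKLHLLHADFLFSKAKVGESDFHPAQKSFKVLFAESFIMNVRQAQETTAVSLGWSQEF
PAIYPEAVAEILFPEISVSIDYSTIMDMYGSIVAKIAKAASVPRQTVEYGMDSDGDDTIQ
QITNDKGLVDQQKHPGVVV
>UNK04 synthetic hypothetical-4 protein of unknown function
MVAGKNLVNIPFSTFEDDIPLSGQLGRTPGQQGDQFTMFKQPTSTELDTAWERQKVGHYA
MEAVYVERHAASQLVVKLFPYEIREKSDFEGLVHKSHVKLMRNDLAELDESIPLAEKGQA
MKR
>UNK05 synthetic hypothetical-5 protein of unknown function
MQLYTQVLGLESQSLEPHQATKSLSLDLRNVAIYEPVHLMPATDHETGWLGNYTRRVIEP
LIGIEKPLPRLNPKGKLHNTDEILEILADVEDPDHVTDLAWLSVWGPILKNVAQLVVHGA
RFKGQGYKDLTNLVESRLVAGEAIAWDIHGRQEDELS
>UNK06 synthetic hypothetical-6 protein of unknown function
MQEQEAVGTEAVIAKPYRHTSELFKYGSRTSSGLASTLRLGRYEVSVMVDANLATQLVTA
RHYAAAVPETFEETMLETSSWDVEDKNEDIDGVAMHGYHHQYDTGLALKLNLMGEQKKNR
LTDVGVGLADLVGR
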