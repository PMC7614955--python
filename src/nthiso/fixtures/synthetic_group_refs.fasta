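>ref_i_0 Synthetic GROUP_I
LVYAHNNQWFYGEMVNHFPGFVSMEMDWMIFDLVMSIIIASEPFPNPGWTQLRPSWQREQ
RICQVNHSNDKGTRLTWQFKGRVCKNRSMWIVLSPGPHRFCRKWMKHFANWIHIKIDFRK
PTGKHWEYVKYMDVFRSRHRCKYSFELQKKEDAHMQMFHSHDMMAHGPETVKIYEWWHEG
SDAFQQSLQTPYYVLTCSPQTEFMHAVTRYYDLGGAPECKSWCSLHCRPMYRFVFVNPYC
>ref_i_1 Synthetic GROUP_I
LVYAHNLQWFYGEMVNHFPGFYSMSMDWMIFDVLMSRIPASSPFPNPGWTQLCPSWCREQ
RICQVNHSPDKGTRITWQFKWRVKKNRSMWIFHSPGPHRFCRKWMFHFACWHHIKIDFRK
PTGKHWEYVVYMYVHKSWHRCKYSFKLQKVEDAHGQWFHAKDMMAVGYSTVYIYEWWHEG
SDAFQQSPQTPYYVLTCSPTTEFMYAVTRYYDLGMAYECKSWCSLHCRPMERVVFVNPYC
>ref_i_2 Synthetic GROUP_I
LVYYHNCQYFIGEMVNHKPGFQSMKMDWMIFDVWMSRIPASYPFPNPGWTQLRPSWCREQ
RIHQVNHSPDQGTRLTWQFKGRIQKNRSMWAVLSPGPHPFCIAWMFHFACWIHFKIDFYK
PTGKHWEYRKYMYVHKSNHRCKYTFKLQKVEDAHDQWFHSHDMMALGPETVYIYEWWHDG
SDAFEQSPQTPYYVLTCKPTTEFMHLVTRYYDLGAAPECKSWCSLHCRPYERFVFVNPYC
>ref_i_3 Synthetic GROUP_I
LMYAHNCQWFYGEMVNHFFGFCSMSMDWMIFDVLMSRIPTSTPFPNPGWTQLRPSWCREQ
RKCQVNHSPDKGTRLTWQFKGRDCKNRSMWICLSPGPHRFCRKWMFHFACWIHIKMDFRK
PTGKHAEYVGYMYVHKSNHRCKYSFCLQKVEDAHDQWFYSHHMMAHGPETVYIYEWWREG
SDRHWRSGQTPYYVLTCSPTTEFMHAVTRYYDFGAAPECKSWCSLHCRPMERFVFVNPYC
>ref_ii_0 Synthetic GROUP_II
LWGSHNIRTKPGEMHNHKPGNLFMSWDWDINWVVYNDIPARESGHTPIWKQCEGKYFRTK
RSPQVVHMPDKGDRLTHNPYSHVDCNHQFMIKFSVESYDFPRNWGFDKKADTHIKVTVRK
RTRDTWQIVKYGEQSYSNVVDTYIIPLMKREIAHAHQPHLFDAMATDPEAVRIYTYFHFG
SDTFQQSEQTDWYALICEPSTEPIHWYTRWYDAMAAPLGFSWESSAREPMYRSVIVHVFS
>ref_ii_1 Synthetic GROUP_II
LWGSHNIITKPGEMHNHKPGNLFMTWDWDNNACLYNDPPAREPGHTPIWTQCEGKYFRTK
RHPQVVHMPWKGDRLTHNFFSWVDCNHNWMIKFSVQSYDFPGNVGFDFKADTSIRVFPRK
YTRLTWQIAKYGEQSYSNVVDTYIIKLRKREIAVKHQPHLFHAMATDPYAVAIYTYNHMG
SDAQQQSGRTDWYALSCEPSTEPIHWYTRWYRQEAAPLGFSWPSSVRCNMHRFVFTHVYS
>ref_ii_2 Synthetic GROUP_II
LWGSHNIITKHGEMHNHKPGNLVWSSRWDINATLYNDIPAREPGHTKIWTICEGKYFRHK
RSPQPVHMMDKTDRLTYNFFSHVGCNHQWMTKFSVEVYDFPRNWGFDFKADTHIKVTVRN
YTRLTWQIVKYGEQSYSNVVDTYENKLMKREIAHAHQPHLFKAMATDPYAVRIYTYFHFG
SDDFQQSPQTDWYALICTPSTEPIHWYTDWYDHEAAPLGFSWPSSVREPMHRFVFTHVYS
>ref_ii_3 Synthetic GROUP_II
LWGSHNIITKPGEMHNYKPGNLFHSSDWDINAVLYNDIPAREPPHTPIWTQCEGKYQRTK
RSIQVVHMPDKGDRLTHCFFSHVTCNHQWMIKFSVESYDFPRNWGFEFKADTHIKVTVRK
YTRLTWQIVKYGEQSYCNVVDTYIIKLMKREIAHAHQPHLFDAMATDPYAVRIYTYFHFG
IDAFQQSGQTDWYALICEPSTEPIHWYTRPYDHGAAILGFSWPSSVREPMHRFVFTHRYS
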