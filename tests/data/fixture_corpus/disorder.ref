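>SYN0000
TMGYVEMWTRPARLCFMRMPVQIPNDCQINHFEITKINYINKPKPMQYENKIFCKTCKYYFAQAHLVCQMDTTLWPWYNGDNESWFNAEIVYPNNCIYKFFRAYVNLSMLHKSCARITAWDKYDQRKCMKVQHCNGQVIWMMSSWYEK
0000000000000000000000011111111111111111111111110000000000000000000000000000000000000000000000000000000000000000000000000000001111111111111111111000
>SYN0001
WHANSRTPDTKTTYAVPLSYMCRFFEEWIDEIHHWVNYHDGCYFKFYEMYMVVSRNNTKWVIKRWCCFKEMMYRGSTQQHRDPWYGHPIRFECLFGWTTNDRPWLENLQIHDYSLFPKPCERCQKASQTVRTDWWQTRVVMTWGAEAKAGGRFWEYNFAHNDEDQCA
00000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0002
LHNWVMPTKQFPFESNIAFTLYWVACNHTHEDHPDSHHQVKSHDTSSVLENNIPGPSCLQCPWTQTIHCRHVLVDEHALQQFENPWVIEGVLYQNDNITDEQQTMIHIQMGFRFFHVLNCHSSNVGECESWDM
0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0003
DTDPCRWRGTHSTLPVEAKEVVIHRLCQRCSMTVQHIRCFMWSTEGGRMFRPVNDVECSLPDRKYPWSTCSPIHPEEVSNSHRFKDIHKLAHTKMDIYMARSIA
00000000000000000000000000000000000000000000000000011111111111111111111100000000000000000000000000011110
>SYN0004
TGWIISDASWYDDHRWTIWGDKCQYDDEEMNYKWSVELWSFTSDCGLEADHIHKRFLRCWYGVGWQFCIRFMDKAYMTDEENVPLWEEQVGGMSGTMRPLMYIWSEVIEGDHDMYYWFFQYTFR
0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000111111111111110000000000000000000
>SYN0005
MKLMWSASHHNYCMFWLVVDSSTYSTRGTRQYRHHHECSSEIWTNYHTWNEGMGCEYINKTDGNTLRTPTYFKFKAQFTRHLQKFANMSDCRRSAQYSLL
0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0006
KCRMMWRYCYNKNAWPAWLDPCNSCSNHFAEGVMERLTSWRDNKTELTPATIQQPKKDNGIERWIKLCSVMCHETTIITCSYKSRVARIVVGNLNTQSQGNIKDEHGPGFKNYMIHKWIFNSWGVVIHGHVHLWQDCFVFHMLCEYKGTLTE
00000000000000000000000000000001111111111111111111111111111111111111111111111111111000000000000000000000000000000000000000000000000000000000000000000000
>SYN0007
LTSQLTIQMHFMHMRTSMCERNTLKFCDQNFIPIIGPVGGLEMVPEFCYHGVHFGICPKYSIRTEEDAHSSILSWGQNPTSISCHFGWKCLCDIKFPLDTDIEWGVYFAAEKEYLTADLEEAGSSMEKPDKTKLTQEPWFVNQHAAQYPISWFDYAVDDGHHAVTQWWYIPSQSQINEYVPSHIMGAIRGQNKRVYSCHMCKDNEGHYKNWAGKVRQIVEKIACSWFCDCSAQSFFGSWSGRRKDHTMDW
0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0008
MHANNETMCEGRSTPWHNPILRVWGRSWPFREILREQDIDAHYNRFFWRLGVLCVKKIGPHMCTFPGEERCSLLFIRVWPGCNNMMCIDVVTLTTHCTNKVYVAALMFINSSCIGGTKLYLS
00000000000111111111111111111111011111111111100000000000000000000000000000000000111111111111111111000011110000000000000000
>SYN0009
YYHKARIAEECCNFYNNMPSHPNQSSNCTYNKELNSLEEMPVTNDTMTRHKKGSIQMKQENDDTTQWPDIFREPTEWRAMHQELLLWWCSEELYMNRLKQDVINYSSTDKTGHVSG
00000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
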