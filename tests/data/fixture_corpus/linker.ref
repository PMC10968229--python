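>SYN0000
TMGYVEMWTRPARLCFMRMPVQIPNDCQINHFEITKINYINKPKPMQYENKIFCKTCKYYFAQAHLVCQMDTTLWPWYNGDNESWFNAEIVYPNNCIYKFFRAYVNLSMLHKSCARITAWDKYDQRKCMKVQHCNGQVIWMMSSWYEK
0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0001
WHANSRTPDTKTTYAVPLSYMCRFFEEWIDEIHHWVNYHDGCYFKFYEMYMVVSRNNTKWVIKRWCCFKEMMYRGSTQQHRDPWYGHPIRFECLFGWTTNDRPWLENLQIHDYSLFPKPCERCQKASQTVRTDWWQTRVVMTWGAEAKAGGRFWEYNFAHNDEDQCA
00000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0002
LHNWVMPTKQFPFESNIAFTLYWVACNHTHEDHPDSHHQVKSHDTSSVLENNIPGPSCLQCPWTQTIHCRHVLVDEHALQQFENPWVIEGVLYQNDNITDEQQTMIHIQMGFRFFHVLNCHSSNVGECESWDM
0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0003
DTDPCRWRGTHSTLPVEAKEVVIHRLCQRCSMTVQHIRCFMWSTEGGRMFRPVNDVECSLPDRKYPWSTCSPIHPEEVSNSHRFKDIHKLAHTKMDIYMARSIA
00000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0004
TGWIISDASWYDDHRWTIWGDKCQYDDEEMNYKWSVELWSFTSDCGLEADHIHKRFLRCWYGVGWQFCIRFMDKAYMTDEENVPLWEEQVGGMSGTMRPLMYIWSEVIEGDHDMYYWFFQYTFR
0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0005
MKLMWSASHHNYCMFWLVVDSSTYSTRGTRQYRHHHECSSEIWTNYHTWNEGMGCEYINKTDGNTLRTPTYFKFKAQFTRHLQKFANMSDCRRSAQYSLL
0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0006
KCRMMWRYCYNKNAWPAWLDPCNSCSNHFAEGVMERLTSWRDNKTELTPATIQQPKKDNGIERWIKLCSVMCHETTIITCSYKSRVARIVVGNLNTQSQGNIKDEHGPGFKNYMIHKWIFNSWGVVIHGHVHLWQDCFVFHMLCEYKGTLTE
00000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0007
LTSQLTIQMHFMHMRTSMCERNTLKFCDQNFIPIIGPVGGLEMVPEFCYHGVHFGICPKYSIRTEEDAHSSILSWGQNPTSISCHFGWKCLCDIKFPLDTDIEWGVYFAAEKEYLTADLEEAGSSMEKPDKTKLTQEPWFVNQHAAQYPISWFDYAVDDGHHAVTQWWYIPSQSQINEYVPSHIMGAIRGQNKRVYSCHMCKDNEGHYKNWAGKVRQIVEKIACSWFCDCSAQSFFGSWSGRRKDHTMDW
0000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0008
MHANNETMCEGRSTPWHNPILRVWGRSWPFREILREQDIDAHYNRFFWRLGVLCVKKIGPHMCTFPGEERCSLLFIRVWPGCNNMMCIDVVTLTTHCTNKVYVAALMFINSSCIGGTKLYLS
00000000000000000000000000000000011111111111100000000000000000000000000000000000000000000000000000000000000000000000000000
>SYN0009
YYHKARIAEECCNFYNNMPSHPNQSSNCTYNKELNSLEEMPVTNDTMTRHKKGSIQMKQENDDTTQWPDIFREPTEWRAMHQELLLWWCSEELYMNRLKQDVINYSSTDKTGHVSG
00000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000000
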