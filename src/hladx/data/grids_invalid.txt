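999066048764759382
099066048764759382G
999029141777631706
909029141777631706X
999001152449390926
990001152449390926W
999039825979190748
999139825979190748Y
999034167211068403
999004167211068403E
999094580730215736
9990905807302157367
999091740029755047
999091040029755047B
999052601815908301
999052611815908301B
999035623012383607
999035620012383607E
999079542205879158
9990795420058791586
99906?048764759382G
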