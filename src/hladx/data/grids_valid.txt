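999066048764759382G
999029141777631706X
999001152449390926W
999039825979190748Y
999034167211068403E
9990945807302157367
999091740029755047B
999052601815908301B
999035623012383607E
9990795422058791586
9990906790377420870
9990787789328792173
9990748526057479382
999044232322183406N
999019834441747661T
999030802300253157L
999057746370643304I
999086454284103664H
999021753377274743H
999008183658492941N
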