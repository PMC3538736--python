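subject,method,left_rbf,right_rbf,diseased_side
1,ASL,295,304,none
2,ASL,456,634,left
3,ASL,191,344,left
4,ASL,289,504,left
5,ASL,374,462,left
6,ASL,269,371,left
1,DCE,535,519,none
2,DCE,321,433,left
3,DCE,313,481,left
4,DCE,566,631,left
5,DCE,504,679,left
6,DCE,330,517,left
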