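subject,kidney,measurement,rbf
2,left,1,456
2,left,2,425
2,left,3,430
2,left,4,433
2,right,1,634
2,right,2,615
2,right,3,651
2,right,4,650
4,left,1,289
4,left,2,286
4,left,3,274
4,left,4,272
4,right,1,504
4,right,2,502
4,right,3,507
4,right,4,509
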