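name,start,width,gc
a,0,5,0.4
a,1,5,0.6
a,2,5,0.6
a,3,5,0.4
a,4,5,0.4
a,5,5,0.6
a,6,5,0.6
a,7,5,0.4
a,8,5,0.4
a,9,5,0.6
a,10,5,0.6
a,11,5,0.4
a,12,5,0.4
a,13,5,0.6
a,14,5,0.6
a,15,5,0.4
a,16,4,0.5
a,17,3,0.6666666666666666
a,18,2,0.5
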