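RES
1b:x-dgal-HEX-1:5
2s:n-acetyl
3b:b-dglc-HEX-1:5|6:a
LIN
1:1d(2+1)2n
2:1o(3+1)3d
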