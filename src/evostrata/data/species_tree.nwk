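((Co,Mb),((Ml,Aq),((Ta,(Hm,Nv)),((((Dp,Is),(Dm,(Pp,Ce))),(Sm,(Hr,(Ct,Lg)))),((Sp,(Bf,Ci)),(Dr,(Xt,(Gg,Hs))))))));
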