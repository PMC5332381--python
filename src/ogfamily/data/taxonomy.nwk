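((((Os)Poales,(Pd,Ma))monocots,(((((At)Brassicaceae)Brassicales,(Tc)Malvales),Vv),Cc)dicots)mesangiosperms,Amb)angiosperms;
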