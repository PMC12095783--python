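class,meningioma,glioma,pituitary
meningioma,704,1,3
glioma,9,1417,0
pituitary,2,0,928
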