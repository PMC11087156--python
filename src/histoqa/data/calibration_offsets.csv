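phantom,group,dx_mm,dy_mm,dz_mm
BCR1,before_refinement,0.55,0.38,-2.11
BCR2,before_refinement,0.30,0.19,-2.19
BCR3,before_refinement,0.15,0.10,-2.22
BCR4,before_refinement,0.09,0.55,-2.55
BCR5,before_refinement,0.08,0.56,-2.50
BCR6,before_refinement,-0.16,0.40,-2.68
ACR1,after_refinement,0.16,-0.28,-0.51
ACR2,after_refinement,0.25,-0.30,-0.55
ACR3,after_refinement,0.18,-0.31,-0.29
ACR4,after_refinement,0.15,-0.18,-0.34
ACR5,after_refinement,0.30,-0.16,0.04
ACR6,after_refinement,0.35,-0.10,-0.63
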