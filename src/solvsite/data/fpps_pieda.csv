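fragment,ligand,total,ES,EX,CTmix,DI,dQ
Phe99,minodronate,-2.8,-2.5,5.0,-1.6,-3.7,0.0047
Phe99,zoledronate,0.10,0.31,0.0010,-0.036,-0.17,0.00
Phe99,risedronate,-0.39,0.086,0.017,-0.090,-0.41,0.00
Phe99,ibandronate,4.4,-7.1,23,-3.0,-8.7,0.013
Phe99,alendronate,0.50,0.61,-0.0010,-0.010,-0.090,0.00
Phe99,pamidronate,0.77,0.85,-0.0010,-0.0090,-0.069,0.00
Leu100,minodronate,-11,-9.8,4.7,-1.7,-4.1,0.019
Leu100,zoledronate,-5.3,-4.4,0.76,-0.45,-1.2,0.0021
Leu100,risedronate,-6.2,-5.1,1.2,-0.57,-1.7,0.0023
Leu100,ibandronate,-6.0,-5.9,4.2,-1.2,-3.1,0.0069
Leu100,alendronate,-4.0,-3.3,1.2,-0.52,-1.3,0.0020
Leu100,pamidronate,-4.9,-4.3,1.1,-0.56,-1.2,0.0032
Thr201,minodronate,-45,-45,10,-3.9,-5.9,0.056
Thr201,zoledronate,-45,-43,6.4,-3.2,-4.7,0.042
Thr201,risedronate,-49,-58,21,-5.2,-6.3,0.067
Thr201,ibandronate,-22,-28,13,-2.9,-4.8,0.035
Thr201,alendronate,-35,-43,16,-5.5,-3.3,0.054
Thr201,pamidronate,-24,-22,0.078,-0.82,-0.81,0.0065
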