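GRS,Morphology,NatArt,EQi
1,Decimetric blocks,Natural,12.2
2,Low coast,Natural,16.6
3,High coast,Natural,15.3
4,Decimetric blocks,Artificial,12.1
5,Low coast,Artificial,11.9
6,High coast,Artificial,8.0
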