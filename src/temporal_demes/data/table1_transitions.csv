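transition,site,resampled,dead,vegetative,reproductive
2010-11,Em01,103,42,33,28
2010-11,Em08,37,16,9,12
2010-11,Em23,104,23,12,69
2010-11,Em25,95,37,11,47
2011-12,Em01,33,20,5,8
2011-12,Em08,56,35,14,7
2011-12,Em23,80,31,10,39
2011-12,Em25,1,,,1
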