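# SYNTHETIC typical %TA (= 100 * tartaric / (tartaric + malic)) values for
# plants and plant products, for plotting assemblage %TA against botanical
# context.  Constructed orders of magnitude only, not measured data.
plant,percent_ta_typical,group
grape (ripe),80,grape_product
wine,85,grape_product
raisin,75,grape_product
vinegar,82,grape_product
tamarind,55,grape_like
pomegranate (some cultivars),45,grape_like
apple,4,orchard_fruit
plum,3,orchard_fruit
cherry,2,orchard_fruit
peach,5,orchard_fruit
leek,1,vegetable
cabbage,1,vegetable
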