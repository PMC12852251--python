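trait_name	trait_class
Milk yield	milk
Milk fat percentage	milk
Milk protein yield	milk
Somatic cell score	health
Bovine tuberculosis susceptibility	health
Tick resistance	health
Carcass weight	meat and carcass
Marbling score	meat and carcass
Body weight gain	production
Feed efficiency	production
Calving ease	reproduction
Conception rate	reproduction
Coat color	exterior
Horn length	exterior
Stature	exterior
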