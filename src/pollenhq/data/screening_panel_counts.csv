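class,count
fungicide,75
herbicide,95
insecticide,89
plant_regulator,3
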