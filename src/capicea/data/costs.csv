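arm,component,category,amount_zar
intervention,compensation,direct,488.00
intervention,training,direct,104.00
intervention,investigations,direct,850.62
intervention,medication_consumables,direct,3725.53
intervention,overheads,indirect,782.00
comparator,compensation,direct,432.00
comparator,training,direct,0.00
comparator,investigations,direct,523.06
comparator,medication_consumables,direct,3223.41
comparator,overheads,indirect,768.00
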