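class,y2020,security,material,spiritual,comprehensive,ld
arable,3919.27,3919.27,4705.12,3919.27,4703.12,3886.83
forest,24887.55,25176.17,23723.93,23985.54,23189.20,24867.71
grass,4198.31,3909.57,4486.15,5037.97,5037.97,4181.84
water,311.17,311.17,373.40,373.40,373.40,350.50
residential,136.49,136.49,153.27,136.49,143.27,155.24
industrial_mining_transport,28.56,28.56,39.36,28.56,34.27,39.09
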