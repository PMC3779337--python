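resource_id,consumer_id
i01,i03
i01,v01
i02,i04
i03,v01
i05,v01
p01,i02
p01,i03
p01,i05
p02,i01
p02,i03
p02,i04
p03,i01
p04,i03
p04,i05
p05,v01
p06,i01
p06,i02
p06,i05
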