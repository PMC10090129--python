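zone_id,zone_class,area_m2,count,count_sd
NT_GRZ,GRZ,4356,2265,159
NT_OZ,OZ,66179,1853,130
RVC_GRZ,GRZ,14637,,
RVC_OZ,OZ,178429,,
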