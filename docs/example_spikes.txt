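# latentlangevin-spikes v1
# design: reaction-time
# time_unit: second
0 0.0 0.4273 5 0.0315 0.1182 0.2047 0.2988 0.3901
1 0.0 0.6118 4 0.0922 0.2540 0.4333 0.5726
2 0.0 0.2495 2 0.0781 0.1904
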