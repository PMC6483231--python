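# Expert-selected limbic-system ROI set (AAL ids), grouped by functional subsystem.
# affective: prefrontal regions associated with affective processing
# executive: cingulate / hippocampal / amygdalar / thalamic regions associated
#            with executive processing
affective	3
affective	4
affective	5
affective	6
affective	7
affective	8
affective	9
affective	10
affective	13
affective	14
affective	15
affective	16
executive	31
executive	32
executive	33
executive	34
executive	35
executive	36
executive	37
executive	38
executive	39
executive	40
executive	41
executive	42
executive	77
executive	78
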