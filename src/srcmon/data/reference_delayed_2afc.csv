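trial_type,resp_expected,resp_unexpected
expected,1732,572
unexpected,898,1406
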