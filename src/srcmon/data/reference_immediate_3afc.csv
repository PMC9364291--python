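trial_type,resp_expected,resp_unexpected,resp_new
expected,1632,248,424
unexpected,398,1483,423
new,160,67,2077
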