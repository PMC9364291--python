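trial_type,resp_expected,resp_unexpected,resp_new
expected,1556,429,319
unexpected,498,1528,278
new,124,69,2111
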