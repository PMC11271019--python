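variable,label
USUBJID,Unique Subject Identifier
VISITNUM,Visit Number
VISIT,Visit Name
EXTRT,Name of Treatment
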