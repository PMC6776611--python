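Document Information,author,,date,,version,,repository,
Path to Section,Section Name,Section Type,Section Definition,Property Name,Property Definition,Value,Data Unit,Data Uncertainty,odML Data Type
/Subject/Scores,Scores,scores,,Date,,,,,date
,,,,Weight,,,g,,float
,,,,Experimenter,,Alice,,,string
,,,,Comment,,,,,text
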