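Document Information,author,Alice,date,2000-01-01,version,1.0,repository,
Path to Section,Section Name,Section Type,Section Definition,Property Name,Property Definition,Value,Data Unit,Data Uncertainty,odML Data Type
/Subject/Scores_2000-01-01,Scores_2000-01-01,scores,,Date,,2000-01-01,,,date
,,,,Weight,,5.0,g,,float
,,,,Experimenter,,Alice,,,string
,,,,Comment,,Blood sample was taken [...],,,text
/Subject/Scores_2000-01-02,Scores_2000-01-02,scores,,Date,,2000-01-02,,,date
,,,,Weight,,5.5,g,,float
,,,,Experimenter,,Bob,,,string
,,,,Comment,,Small scratch at the right ear,,,text
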