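(ABSTRACT:"www" OR ABSTRACT:"http") AND (ABSTRACT:"database" OR ABSTRACT:"resource" OR ABSTRACT:"knowledgebase") AND (LANG:"eng" OR LANG:"en") AND (PUB_YEAR:[2011 TO 2021]) NOT (ABSTRACT:"clinicaltrials.gov")
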