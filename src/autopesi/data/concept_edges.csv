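child,parent
64572001,138875005
363346000,64572001
84114007,64572001
413839001,64572001
93880001,363346000
254837009,363346000
363406005,363346000
399068003,363346000
118600007,363346000
93143009,363346000
363418001,363346000
372244006,363346000
254701007,363346000
128462008,363346000
254626006,93880001
109989006,93143009
42343007,84114007
417996009,84114007
418304008,84114007
703272007,84114007
56675007,84114007
10633002,42343007
13645005,413839001
195967001,413839001
51615001,413839001
233703007,413839001
190905008,413839001
87433001,13645005
63480004,13645005
195949008,195967001
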