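#! name: staggered_fixation_12pt
#! plate: 96-well
#! fixation_horizon: 1440
# Reverse schedule: well k is stimulated with a single 10-s blue pulse
# 120*k seconds before the common endpoint (horizon 1440 s), so every
# well can be fixed simultaneously at the end of the experiment.
target,start,duration,red,green,blue,repeats,interval,message,buzzer
A01,1320,10,0,0,255,,,,
A02,1200,10,0,0,255,,,,
A03,1080,10,0,0,255,,,,
A04,960,10,0,0,255,,,,
A05,840,10,0,0,255,,,,
A06,720,10,0,0,255,,,,
A07,600,10,0,0,255,,,,
A08,480,10,0,0,255,,,,
A09,360,10,0,0,255,,,,
A10,240,10,0,0,255,,,,
A11,120,10,0,0,255,,,,
A12,0,10,0,0,255,,,fix all wells now,1
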