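#! name: single_pulse_fixation_ladder
#! plate: 96-well
#! fixation_horizon: 720
# Single 2-s blue pulse staggered at 1-min resolution over 12 wells
# (horizon 720 s); fixation of the whole ladder happens at the end.
target,start,duration,red,green,blue,repeats,interval,message,buzzer
A01,660,2,0,0,255,,,,
A02,600,2,0,0,255,,,,
A03,540,2,0,0,255,,,,
A04,480,2,0,0,255,,,,
A05,420,2,0,0,255,,,,
A06,360,2,0,0,255,,,,
A07,300,2,0,0,255,,,,
A08,240,2,0,0,255,,,,
A09,180,2,0,0,255,,,,
A10,120,2,0,0,255,,,,
A11,60,2,0,0,255,,,,
A12,0,2,0,0,255,,,,
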