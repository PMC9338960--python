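#! name: pulse_train_phase_shift
#! plate: 96-well
# Two pairs of wells receive a 3-s blue pulse every 5 min for 1 h;
# the second pair starts 30 min later (loop end times are absolute,
# end-exclusive).
target,start,duration,red,green,blue,repeats,interval,message,buzzer
A01,0,3,0,0,255,01:00:00,00:05:00,,
B01,0,3,0,0,255,01:00:00,00:05:00,,
C01,00:30:00,3,0,0,255,01:00:00,00:05:00,,
D01,00:30:00,3,0,0,255,01:00:00,00:05:00,,
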