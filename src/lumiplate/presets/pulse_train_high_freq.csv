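#! name: pulse_train_high_freq
#! plate: 96-well
# High-frequency train: 10-s blue pulses every 2 min for 84 min
# (end-exclusive: 42 pulses at t = 0, 120, ..., 4920 s).
target,start,duration,red,green,blue,repeats,interval,message,buzzer
A01,0,10,0,0,255,01:24:00,00:02:00,,
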