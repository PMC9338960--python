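#! name: pulse_train_low_freq
#! plate: 96-well
# Low-frequency train: 10-s blue pulses every 20 min for 84 min
# (end-exclusive: 5 pulses at t = 0, 1200, 2400, 3600, 4800 s).
target,start,duration,red,green,blue,repeats,interval,message,buzzer
A01,0,10,0,0,255,01:24:00,00:20:00,,
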