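material,kv,dose_pct,fat_ring,delta_base,der,alpha
iodine,140,100,False,-5.72,2.48,26.45
iodine,140,120,False,-5.77,2.48,26.45
iodine,140,200,False,-7.25,2.48,26.43
iodine,120,100,False,-5.01,2.08,26.23
iodine,120,120,False,-5.78,2.08,26.17
iodine,120,200,False,-7.45,2.09,26.18
iodine,140,100,True,-4.20,2.52,26.94
iodine,140,120,True,-4.95,2.50,26.65
iodine,140,200,True,-6.55,2.50,26.59
iodine,120,100,True,-4.47,2.11,26.40
iodine,120,120,True,-5.47,2.11,26.42
iodine,120,200,True,-7.72,2.12,26.33
iron,140,100,False,-3.85,2.18,4.30
iron,140,120,False,-4.16,2.15,4.30
iron,140,200,False,-5.77,2.17,4.30
iron,120,100,False,-4.24,1.95,4.03
iron,120,120,False,-4.58,1.91,4.05
iron,120,200,False,-5.64,1.92,4.02
iron,140,100,True,-3.39,2.20,4.36
iron,140,120,True,-3.19,2.22,4.35
iron,140,200,True,-4.23,2.16,4.32
iron,120,100,True,-2.66,1.93,4.12
iron,120,120,True,-3.50,1.96,4.07
iron,120,200,True,-4.64,1.91,4.09
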