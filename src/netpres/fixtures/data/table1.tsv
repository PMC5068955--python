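Modules	Size	ME %	% Consistent Genes
M27	62	23.4	0.71
M26	67	30.1	0.64
M25	68	28.1	0.49
M24	73	26.5	0.82
M23	90	28.1	0.80
M22	91	25.8	0.79
M21	96	26.2	0.82
M20	98	28.7	0.63
M19	131	28.4	0.93
M18	141	20.7	0.42
M17	158	24.1	0.82
M16	159	25.2	0.53
M15	160	24.7	0.86
M14	185	21.4	0.67
M13	186	25.8	0.51
M12	209	29.3	0.45
M11	217	27.1	0.60
M10	270	28.6	0.60
M9	282	24.4	0.70
M8	292	25.0	0.58
M7	295	22.9	0.60
M6	369	22.0	0.65
M5	394	26.8	0.69
M4	439	22.6	0.46
M3	449	17.1	0.54
M2	854	18.1	0.61
M1	967	24.2	0.74
M0 (unassigned genes)	1088	3.2	0.70
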