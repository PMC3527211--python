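# In(1)Be sex-ratio distortion crosses: X-line females x Y-line males, F1 male
# test crosses scored for adult progeny sex ratio. Female counts are
# reconstructed from the published per-cross K and progeny total as
# round(K * N); the egg count applies to the RG11N x ZS30 mating, with the
# conservative egg-assay female count taken from its paired adult count.
x_line	y_line	role	f1_males	females	males	eggs
GA191N	ZS30	experimental	9	781	670
GA191N	C5	experimental	5	200	155
GA191N	C17	experimental	4	188	156
GA191N	K12	experimental	5	253	236
RG10	ZS53	experimental	5	408	343
RG10	C5	experimental	4	201	178
KR39	K12	experimental	5	298	269
KR39	C17	experimental	5	258	199
RG11N	C17	experimental	5	217	200
RG11N	K12	experimental	4	123	98
RG11N	ZS30	experimental	18	1428	1212	2724
RG11N	ZS30	control	12	663	642
RG22	C17	control	5	249	229
RG22	ZS53	control	4	177	181
RG22	C5	control	5	264	259
RG35	ZS30	control	5	367	337
RG35	K12	control	4	125	104
KR42	K12	control	5	204	196
KR42	C5	control	5	184	196
KR42	C17	control	5	227	217
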