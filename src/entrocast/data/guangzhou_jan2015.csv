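date,actual,arima,ann,esm,cfm
2015/1/22,58.2,101.6861,61.6869,114.865,82.8862
2015/1/23,64.4,37.9755,61.6923,98.6254,64.0614
2015/1/24,73.6,56.3128,61.6964,89.1382,66.3927
2015/1/25,68.8,43.7694,61.6993,86.038,62.7086
2015/1/26,68.3,41.9564,61.7012,81.2968,61.2402
2015/1/27,64.8,43.2804,61.7021,77.4207,60.7125
2015/1/28,49.3,38.7611,61.7022,72.8985,58.6417
2015/1/29,51.7,41.4545,61.7016,62.6025,57.0409
2015/1/30,32.8,38.5742,61.7004,56.4024,54.9964
2015/1/31,35.6,40.069,61.6986,43.6473,52.5709
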