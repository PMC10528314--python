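# Breaking stress (GPa) of 64 single carbon fibers, gauge length 10 mm
# Source: Cheng & Traylor (1970) classical dataset; n = 64
1.901
2.132
2.203
2.228
2.257
2.350
2.361
2.396
2.397
2.445
2.454
2.454
2.474
2.518
2.522
2.525
2.532
2.575
2.614
2.616
2.618
2.624
2.659
2.675
2.738
2.740
2.856
2.917
2.928
2.937
2.937
2.977
2.996
3.030
3.125
3.139
3.145
3.220
3.223
3.235
3.243
3.264
3.272
3.294
3.332
3.346
3.377
3.408
3.435
3.493
3.501
3.537
3.554
3.562
3.628
3.852
3.871
3.886
3.971
4.024
4.027
4.225
4.395
5.020
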