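contour_set,case,observer,seconds,scratch_seconds,normalized_printed
1,1,1,703,730,0.963
1,1,2,385,420,0.917
1,1,3,642,631,1.017
1,1,4,575,584,0.985
1,1,AVE,,,0.970
1,2,1,601,730,0.823
1,2,2,293,420,0.698
1,2,3,591,631,0.937
1,2,4,551,584,0.943
1,2,AVE,,,0.850
1,3,1,517,730,0.708
1,3,2,227,420,0.540
1,3,3,465,631,0.737
1,3,4,366,584,0.627
1,3,AVE,,,0.653
1,4,1,350,730,0.479
1,4,2,180,420,0.429
1,4,3,365,631,0.578
1,4,4,283,584,0.485
1,4,AVE,,,0.493
1,5,1,256,730,0.351
1,5,2,119,420,0.283
1,5,3,233,631,0.369
1,5,4,200,584,0.342
1,5,AVE,,,0.336
2,1,1,369,730,0.505
2,1,2,156,420,0.371
2,1,3,407,631,0.645
2,1,4,300,584,0.514
2,1,AVE,,,0.509
2,2,1,356,730,0.488
2,2,2,181,420,0.431
2,2,3,405,631,0.642
2,2,4,296,584,0.507
2,2,AVE,,,0.517
2,3,1,375,730,0.514
2,3,2,198,420,0.471
2,3,3,406,631,0.643
2,3,4,287,584,0.491
2,3,AVE,,,0.530
2,4,1,366,730,0.501
2,4,2,180,420,0.429
2,4,3,399,631,0.632
2,4,4,304,584,0.521
2,4,AVE,,,0.521
2,5,1,378,730,0.518
2,5,2,197,420,0.469
2,5,3,399,631,0.632
2,5,4,291,584,0.498
2,5,AVE,,,0.529
2,6,1,371,730,0.508
2,6,2,200,420,0.476
2,6,3,403,631,0.639
2,6,4,297,584,0.509
2,6,AVE,,,0.533
2,7,1,367,730,0.503
2,7,2,220,420,0.524
2,7,3,405,631,0.642
2,7,4,303,584,0.519
2,7,AVE,,,0.547
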