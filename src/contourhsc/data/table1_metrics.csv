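contour_set,case,observer,hsc,dsc
1,1,1,0.000,0.839
1,1,2,0.000,0.839
1,1,3,0.000,0.834
1,1,4,0.000,0.847
1,1,AVE,0.000,0.840
1,2,1,0.110,0.843
1,2,2,0.110,0.844
1,2,3,0.109,0.834
1,2,4,0.111,0.847
1,2,AVE,0.110,0.842
1,3,1,0.293,0.844
1,3,2,0.294,0.844
1,3,3,0.292,0.838
1,3,4,0.297,0.849
1,3,AVE,0.294,0.844
1,4,1,0.503,0.847
1,4,2,0.507,0.848
1,4,3,0.506,0.845
1,4,4,0.510,0.851
1,4,AVE,0.506,0.848
1,5,1,0.700,0.848
1,5,2,0.702,0.848
1,5,3,0.701,0.845
1,5,4,0.705,0.849
1,5,AVE,0.702,0.848
2,1,1,0.460,0.638
2,1,2,0.462,0.635
2,1,3,0.461,0.634
2,1,4,0.466,0.640
2,1,AVE,0.462,0.637
2,2,1,0.461,0.723
2,2,2,0.461,0.726
2,2,3,0.459,0.720
2,2,4,0.465,0.730
2,2,AVE,0.461,0.725
2,3,1,0.462,0.759
2,3,2,0.464,0.765
2,3,3,0.459,0.755
2,3,4,0.467,0.766
2,3,AVE,0.463,0.761
2,4,1,0.460,0.797
2,4,2,0.463,0.802
2,4,3,0.461,0.797
2,4,4,0.464,0.804
2,4,AVE,0.462,0.800
2,5,1,0.461,0.841
2,5,2,0.464,0.847
2,5,3,0.459,0.838
2,5,4,0.465,0.848
2,5,AVE,0.462,0.844
2,6,1,0.458,0.888
2,6,2,0.464,0.897
2,6,3,0.460,0.887
2,6,4,0.464,0.896
2,6,AVE,0.461,0.892
2,7,1,0.458,0.945
2,7,2,0.460,0.947
2,7,3,0.461,0.944
2,7,4,0.465,0.952
2,7,AVE,0.461,0.947
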