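r,g,b
1.000000,0.000000,0.000000
1.000000,0.011765,0.000000
1.000000,0.023529,0.000000
1.000000,0.035294,0.000000
1.000000,0.047059,0.000000
1.000000,0.058824,0.000000
1.000000,0.070588,0.000000
1.000000,0.082353,0.000000
1.000000,0.094118,0.000000
1.000000,0.105882,0.000000
1.000000,0.117647,0.000000
1.000000,0.129412,0.000000
1.000000,0.141176,0.000000
1.000000,0.152941,0.000000
1.000000,0.164706,0.000000
1.000000,0.176471,0.000000
1.000000,0.188235,0.000000
1.000000,0.200000,0.000000
1.000000,0.211765,0.000000
1.000000,0.223529,0.000000
1.000000,0.235294,0.000000
1.000000,0.247059,0.000000
1.000000,0.258824,0.000000
1.000000,0.270588,0.000000
1.000000,0.282353,0.000000
1.000000,0.294118,0.000000
1.000000,0.305882,0.000000
1.000000,0.317647,0.000000
1.000000,0.329412,0.000000
1.000000,0.341176,0.000000
1.000000,0.352941,0.000000
1.000000,0.364706,0.000000
1.000000,0.376471,0.000000
1.000000,0.388235,0.000000
1.000000,0.400000,0.000000
1.000000,0.411765,0.000000
1.000000,0.423529,0.000000
1.000000,0.435294,0.000000
1.000000,0.447059,0.000000
1.000000,0.458824,0.000000
1.000000,0.470588,0.000000
1.000000,0.482353,0.000000
1.000000,0.494118,0.000000
1.000000,0.505882,0.000000
1.000000,0.517647,0.000000
1.000000,0.529412,0.000000
1.000000,0.541176,0.000000
1.000000,0.552941,0.000000
1.000000,0.564706,0.000000
1.000000,0.576471,0.000000
1.000000,0.588235,0.000000
1.000000,0.600000,0.000000
1.000000,0.611765,0.000000
1.000000,0.623529,0.000000
1.000000,0.635294,0.000000
1.000000,0.647059,0.000000
1.000000,0.658824,0.000000
1.000000,0.670588,0.000000
1.000000,0.682353,0.000000
1.000000,0.694118,0.000000
1.000000,0.705882,0.000000
1.000000,0.717647,0.000000
1.000000,0.729412,0.000000
1.000000,0.741176,0.000000
1.000000,0.752941,0.000000
1.000000,0.764706,0.000000
1.000000,0.776471,0.000000
1.000000,0.788235,0.000000
1.000000,0.800000,0.000000
1.000000,0.811765,0.000000
1.000000,0.823529,0.000000
1.000000,0.835294,0.000000
1.000000,0.847059,0.000000
1.000000,0.858824,0.000000
1.000000,0.870588,0.000000
1.000000,0.882353,0.000000
1.000000,0.894118,0.000000
1.000000,0.905882,0.000000
1.000000,0.917647,0.000000
1.000000,0.929412,0.000000
1.000000,0.941176,0.000000
1.000000,0.952941,0.000000
1.000000,0.964706,0.000000
1.000000,0.976471,0.000000
1.000000,0.988235,0.000000
1.000000,1.000000,0.000000
0.988235,0.988235,0.011765
0.976471,0.976471,0.023529
0.964706,0.964706,0.035294
0.952941,0.952941,0.047059
0.941176,0.941176,0.058824
0.929412,0.929412,0.070588
0.917647,0.917647,0.082353
0.905882,0.905882,0.094118
0.894118,0.894118,0.105882
0.882353,0.882353,0.117647
0.870588,0.870588,0.129412
0.858824,0.858824,0.141176
0.847059,0.847059,0.152941
0.835294,0.835294,0.164706
0.823529,0.823529,0.176471
0.811765,0.811765,0.188235
0.800000,0.800000,0.200000
0.788235,0.788235,0.211765
0.776471,0.776471,0.223529
0.764706,0.764706,0.235294
0.752941,0.752941,0.247059
0.741176,0.741176,0.258824
0.729412,0.729412,0.270588
0.717647,0.717647,0.282353
0.705882,0.705882,0.294118
0.694118,0.694118,0.305882
0.682353,0.682353,0.317647
0.670588,0.670588,0.329412
0.658824,0.658824,0.341176
0.647059,0.647059,0.352941
0.635294,0.635294,0.364706
0.623529,0.623529,0.376471
0.611765,0.611765,0.388235
0.600000,0.600000,0.400000
0.588235,0.588235,0.411765
0.576471,0.576471,0.423529
0.564706,0.564706,0.435294
0.552941,0.552941,0.447059
0.541176,0.541176,0.458824
0.529412,0.529412,0.470588
0.517647,0.517647,0.482353
0.505882,0.505882,0.494118
0.494118,0.494118,0.505882
0.482353,0.482353,0.517647
0.470588,0.470588,0.529412
0.458824,0.458824,0.541176
0.447059,0.447059,0.552941
0.435294,0.435294,0.564706
0.423529,0.423529,0.576471
0.411765,0.411765,0.588235
0.400000,0.400000,0.600000
0.388235,0.388235,0.611765
0.376471,0.376471,0.623529
0.364706,0.364706,0.635294
0.352941,0.352941,0.647059
0.341176,0.341176,0.658824
0.329412,0.329412,0.670588
0.317647,0.317647,0.682353
0.305882,0.305882,0.694118
0.294118,0.294118,0.705882
0.282353,0.282353,0.717647
0.270588,0.270588,0.729412
0.258824,0.258824,0.741176
0.247059,0.247059,0.752941
0.235294,0.235294,0.764706
0.223529,0.223529,0.776471
0.211765,0.211765,0.788235
0.200000,0.200000,0.800000
0.188235,0.188235,0.811765
0.176471,0.176471,0.823529
0.164706,0.164706,0.835294
0.152941,0.152941,0.847059
0.141176,0.141176,0.858824
0.129412,0.129412,0.870588
0.117647,0.117647,0.882353
0.105882,0.105882,0.894118
0.094118,0.094118,0.905882
0.082353,0.082353,0.917647
0.070588,0.070588,0.929412
0.058824,0.058824,0.941176
0.047059,0.047059,0.952941
0.035294,0.035294,0.964706
0.023529,0.023529,0.976471
0.011765,0.011765,0.988235
0.000000,0.000000,1.000000
0.000000,0.000000,0.988235
0.000000,0.000000,0.976471
0.000000,0.000000,0.964706
0.000000,0.000000,0.952941
0.000000,0.000000,0.941176
0.000000,0.000000,0.929412
0.000000,0.000000,0.917647
0.000000,0.000000,0.905882
0.000000,0.000000,0.894118
0.000000,0.000000,0.882353
0.000000,0.000000,0.870588
0.000000,0.000000,0.858824
0.000000,0.000000,0.847059
0.000000,0.000000,0.835294
0.000000,0.000000,0.823529
0.000000,0.000000,0.811765
0.000000,0.000000,0.800000
0.000000,0.000000,0.788235
0.000000,0.000000,0.776471
0.000000,0.000000,0.764706
0.000000,0.000000,0.752941
0.000000,0.000000,0.741176
0.000000,0.000000,0.729412
0.000000,0.000000,0.717647
0.000000,0.000000,0.705882
0.000000,0.000000,0.694118
0.000000,0.000000,0.682353
0.000000,0.000000,0.670588
0.000000,0.000000,0.658824
0.000000,0.000000,0.647059
0.000000,0.000000,0.635294
0.000000,0.000000,0.623529
0.000000,0.000000,0.611765
0.000000,0.000000,0.600000
0.000000,0.000000,0.588235
0.000000,0.000000,0.576471
0.000000,0.000000,0.564706
0.000000,0.000000,0.552941
0.000000,0.000000,0.541176
0.000000,0.000000,0.529412
0.000000,0.000000,0.517647
0.000000,0.000000,0.505882
0.000000,0.000000,0.494118
0.000000,0.000000,0.482353
0.000000,0.000000,0.470588
0.000000,0.000000,0.458824
0.000000,0.000000,0.447059
0.000000,0.000000,0.435294
0.000000,0.000000,0.423529
0.000000,0.000000,0.411765
0.000000,0.000000,0.400000
0.000000,0.000000,0.388235
0.000000,0.000000,0.376471
0.000000,0.000000,0.364706
0.000000,0.000000,0.352941
0.000000,0.000000,0.341176
0.000000,0.000000,0.329412
0.000000,0.000000,0.317647
0.000000,0.000000,0.305882
0.000000,0.000000,0.294118
0.000000,0.000000,0.282353
0.000000,0.000000,0.270588
0.000000,0.000000,0.258824
0.000000,0.000000,0.247059
0.000000,0.000000,0.235294
0.000000,0.000000,0.223529
0.000000,0.000000,0.211765
0.000000,0.000000,0.200000
0.000000,0.000000,0.188235
0.000000,0.000000,0.176471
0.000000,0.000000,0.164706
0.000000,0.000000,0.152941
0.000000,0.000000,0.141176
0.000000,0.000000,0.129412
0.000000,0.000000,0.117647
0.000000,0.000000,0.105882
0.000000,0.000000,0.094118
0.000000,0.000000,0.082353
0.000000,0.000000,0.070588
0.000000,0.000000,0.058824
0.000000,0.000000,0.047059
0.000000,0.000000,0.035294
0.000000,0.000000,0.023529
0.000000,0.000000,0.011765
0.000000,0.000000,0.000000
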