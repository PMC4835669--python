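emotion,dim1,dim2,dim3
anger,-0.133,-0.588,-0.296
fear,-0.386,-0.389,-0.264
sadness,-0.412,0.095,-0.481
happiness,0.794,-0.347,0.273
disgust,-0.478,-0.165,0.409
hope,0.795,0.163,-0.182
love,0.753,-0.335,-0.159
hate,-0.548,-0.046,0.193
contempt,-0.483,0.256,0.28
guilt,-0.19,0.484,-0.199
compassion,0.315,0.537,0.162
shame,0.043,0.192,-0.559
gratefulness,0.652,0.312,0.256
envy,-0.277,0.183,0.496
disappointment,-0.345,0.183,-0.237
jealousy,-0.101,-0.535,0.308
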