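,anger,fear,sadness,happiness,disgust,hope,love,hate,contempt,guilt,compassion,shame,gratefulness,envy,disappointment,jealousy
anger,0.0,11.3,33.6,92.1,28.8,78.4,88.7,16.9,30.0,26.9,59.9,20.8,74.1,30.8,28.6,9.8
fear,11.3,0.0,28.8,92.3,25.8,77.5,89.3,18.0,28.3,21.0,56.9,16.9,72.4,25.3,22.7,15.2
sadness,33.6,28.8,0.0,97.2,15.2,77.2,93.9,22.1,13.1,10.1,47.0,16.5,66.1,21.5,9.2,27.2
happiness,92.1,92.3,97.2,0.0,87.2,23.8,18.8,100.9,96.5,96.8,57.2,88.4,40.9,114.0,94.8,96.2
disgust,28.8,25.8,15.2,87.2,0.0,67.9,86.0,21.5,10.3,18.8,40.9,17.2,58.4,36.6,18.2,23.8
hope,78.4,77.5,77.2,23.8,67.9,0.0,28.2,84.1,77.1,78.2,34.1,70.8,17.2,96.4,75.9,80.7
love,88.7,89.3,93.9,18.8,86.0,28.2,0.0,97.9,94.8,92.6,56.0,84.0,42.0,114.2,90.5,93.0
hate,16.9,18.0,22.1,100.9,21.5,84.1,97.9,0.0,17.2,18.4,59.9,18.2,76.6,31.7,20.8,8.0
contempt,30.0,28.3,13.1,96.5,10.3,77.1,94.8,17.2,0.0,18.3,49.3,20.1,67.0,29.1,18.8,22.2
guilt,26.9,21.0,10.1,96.8,18.8,78.2,92.6,18.4,18.3,0.0,50.2,10.3,68.8,44.7,3.2,22.3
compassion,59.9,56.9,47.0,57.2,40.9,34.1,56.0,59.9,49.3,50.2,0.0,45.6,19.9,72.6,47.4,59.1
shame,20.8,16.9,16.5,88.4,17.2,70.8,84.0,18.2,20.1,10.3,45.6,0.0,62.8,45.8,10.0,18.3
gratefulness,74.1,72.4,66.1,40.9,58.4,17.2,42.0,76.6,67.0,68.8,19.9,62.8,0.0,87.6,66.1,74.6
envy,30.8,25.3,21.5,114.0,36.6,96.4,114.2,31.7,29.1,44.7,72.6,45.8,87.6,0.0,28.0,23.6
disappointment,28.6,22.7,9.2,94.8,18.2,75.9,90.5,20.8,18.8,3.2,47.4,10.0,66.1,28.0,0.0,24.3
jealousy,9.8,15.2,27.2,96.2,23.8,80.7,93.0,8.0,22.2,22.3,59.1,18.3,74.6,23.6,24.3,0.0
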