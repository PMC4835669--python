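emotion,aspect,mean,sd,n
anger,valence,25.3,19.4,187
anger,arousal,79.4,16.9,187
anger,control,47.7,27.4,187
anger,utility,32.4,23.1,187
fear,valence,18.1,17.8,187
fear,arousal,75.6,18.7,187
fear,control,50.0,24.9,187
fear,utility,39.9,24.4,187
sadness,valence,17.4,17.3,187
sadness,arousal,47.1,26.6,187
sadness,control,49.9,25.6,187
sadness,utility,36.1,21.9,187
happiness,valence,91.8,12.0,187
happiness,arousal,69.1,30.4,187
happiness,control,73.9,62.2,187
happiness,utility,89.5,11.0,187
disgust,valence,26.1,17.5,187
disgust,arousal,53.8,21.9,187
disgust,control,60.4,22.6,187
disgust,utility,35.9,16.8,187
hope,valence,77.1,17.4,187
hope,arousal,53.6,28.1,187
hope,control,71.7,20.4,187
hope,utility,79.5,16.9,187
love,valence,91.2,14.9,187
love,arousal,67.9,33.7,187
love,control,55.2,31.9,187
love,utility,90.2,14.3,187
hate,valence,18.7,18.2,187
hate,arousal,65.9,21.7,187
hate,control,48.8,24.3,187
hate,utility,24.7,20.7,187
contempt,valence,22.1,17.8,187
contempt,arousal,51.6,43.8,187
contempt,control,57.2,23.7,187
contempt,utility,27.4,17.8,187
guilt,valence,15.6,13.9,187
guilt,arousal,55.4,24.4,187
guilt,control,45.2,22.9,187
guilt,utility,39.0,23.5,187
compassion,valence,51.4,20.6,187
compassion,arousal,39.1,21.0,187
compassion,control,63.4,20.8,187
compassion,utility,64.5,19.7,187
shame,valence,24.3,15.9,187
shame,arousal,60.6,20.9,187
shame,control,45.5,23.7,187
shame,utility,40.9,20.8,187
gratefulness,valence,68.3,18.3,187
gratefulness,arousal,40.4,23.9,187
gratefulness,control,69.2,20.6,187
gratefulness,utility,73.0,16.2,187
envy,valence,22.9,16.2,187
envy,arousal,56.5,49.3,187
envy,control,65.8,24.6,187
envy,utility,22.9,18.5,187
disappointment,valence,17.3,14.1,187
disappointment,arousal,53.5,25.6,187
disappointment,control,45.3,24.7,187
disappointment,utility,41.0,20.3,187
jealousy,valence,23.9,17.7,187
jealousy,arousal,71.7,19.7,187
jealousy,control,48.0,26.6,187
jealousy,utility,26.5,21.7,187
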