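sex,age_group,share
male,18-34,15.2
male,35-54,17.2
male,55-74,13.3
male,75+,2.9
female,18-34,14.5
female,35-54,16.9
female,55-74,14.7
female,75+,5.3
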