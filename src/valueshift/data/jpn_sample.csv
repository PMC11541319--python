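sex,age_group,share
male,18-34,9.7
male,35-54,15.5
male,55-74,15.5
male,75+,1.3
female,18-34,12.7
female,35-54,25.6
female,55-74,17.7
female,75+,2.1
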