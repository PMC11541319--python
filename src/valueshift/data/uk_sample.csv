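sex,age_group,share
male,18-34,13.9
male,35-54,13.9
male,55-74,12.5
male,75+,3.1
female,18-34,18.1
female,35-54,16.9
female,55-74,16.0
female,75+,5.6
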