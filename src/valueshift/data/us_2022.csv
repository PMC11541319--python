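sex,age_group,share
male,18-34,14.9
male,35-54,16.3
male,55-74,13.9
male,75+,3.9
female,18-34,14.5
female,35-54,16.2
female,55-74,15.1
female,75+,5.2
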