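sex,age_group,share
male,18-34,15.6
male,35-54,17.5
male,55-74,11.5
male,75+,3.3
female,18-34,15.7
female,35-54,17.7
female,55-74,12.7
female,75+,6.0
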