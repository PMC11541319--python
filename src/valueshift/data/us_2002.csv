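sex,age_group,share
male,18-34,16.2
male,35-54,19.4
male,55-74,10.1
male,75+,2.9
female,18-34,15.7
female,35-54,19.9
female,55-74,11.0
female,75+,4.8
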