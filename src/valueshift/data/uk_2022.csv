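sex,age_group,share
male,18-34,13.8
male,35-54,16.0
male,55-74,14.0
male,75+,5.1
female,18-34,13.3
female,35-54,16.4
female,55-74,14.8
female,75+,6.6
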