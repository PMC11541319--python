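sex,age_group,share
male,18-34,16.1
male,35-54,16.5
male,55-74,7.5
male,75+,2.0
female,18-34,22.3
female,35-54,22.2
female,55-74,10.0
female,75+,3.3
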