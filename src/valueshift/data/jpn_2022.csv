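sex,age_group,share
male,18-34,9.9
male,35-54,15.9
male,55-74,14.8
male,75+,7.6
female,18-34,9.5
female,35-54,15.4
female,55-74,15.5
female,75+,11.4
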