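date
2020-01-01
2020-01-13
2020-02-11
2020-02-23
2020-02-24
2020-03-20
2020-04-29
2020-05-03
2020-05-04
2020-05-05
2020-05-06
2020-07-23
2020-07-24
2020-08-10
2020-09-21
2020-09-22
2020-11-03
2020-11-23
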