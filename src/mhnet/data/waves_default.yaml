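# Default epidemic-wave segmentation of the 2021-03-02 .. 2022-01-10
# analysis range, read off the national case/death curves. Windows that
# start before wave 1 (March 2021) fall in no wave and are excluded from
# wave summaries.
waves:
  - label: "1"
    start: 2021-04-01
    end: 2021-07-01
  - label: "2"
    start: 2021-07-02
    end: 2021-11-11
  - label: "3"
    start: 2021-11-12
    end: 2022-01-10
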