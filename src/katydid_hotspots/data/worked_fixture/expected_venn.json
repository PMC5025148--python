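{
 "count_only": 2,
 "score_only": 0,
 "biodiversity_only": 0,
 "count_score": 0,
 "count_biodiversity": 2,
 "score_biodiversity": 0,
 "all_three": 1,
 "total_flagged": 5
}
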