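[
 {
  "item_id": "Ln1",
  "construct": "loneliness",
  "min_score": 1,
  "max_score": 3
 },
 {
  "item_id": "Ln2",
  "construct": "loneliness",
  "min_score": 1,
  "max_score": 3
 },
 {
  "item_id": "Ln3",
  "construct": "loneliness",
  "min_score": 1,
  "max_score": 3
 },
 {
  "item_id": "PHQ1",
  "construct": "depression",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "PHQ2",
  "construct": "depression",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "PHQ3",
  "construct": "depression",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "PHQ4",
  "construct": "depression",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "PHQ5",
  "construct": "depression",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "PHQ6",
  "construct": "depression",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "PHQ7",
  "construct": "depression",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "PHQ8",
  "construct": "depression",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "PHQ9",
  "construct": "depression",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "GAD1",
  "construct": "anxiety",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "GAD2",
  "construct": "anxiety",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "GAD3",
  "construct": "anxiety",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "GAD4",
  "construct": "anxiety",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "GAD5",
  "construct": "anxiety",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "GAD6",
  "construct": "anxiety",
  "min_score": 0,
  "max_score": 3
 },
 {
  "item_id": "GAD7",
  "construct": "anxiety",
  "min_score": 0,
  "max_score": 3
 }
]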