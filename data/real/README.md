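# Real datasets (not redistributed)

The original behavioural datasets are published by their authors and are
not shipped with this package.  To run the real-data analyses, download
them and place CSV exports here:

- `cpc15.csv` — CPC15 aggregate data in the `cpc15` dialect: columns
  `Problem, Ha, pHa, La, Hb, pHb, Lb, LotShape, LotNum, Amb, Corr,
  Feedback, block, N, B_rate`, one row per (problem, block).
- `cpc18.csv` — CPC18 in the `cpc18` dialect (same columns with
  `GameID`, `LotShapeA/LotNumA`, `LotShapeB/LotNumB`); rows whose gamble A
  carries a lottery shape are filtered out automatically.
- `choices13k.csv` — choices13k in the `choices13k` dialect: columns
  `problem_id, Ha, pHa, La, Hb, pHb, Lb, LotShapeB, LotNumB, Amb, Corr,
  Feedback, Block, n, bRate`.

Column mappings live in `choicebias.data`; adjust there if your export
uses different headers.
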