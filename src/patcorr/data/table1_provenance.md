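# Screening fixture provenance

`table1_screening.csv` transcribes the published MIMIC screening table
(seven categories, 578 record IDs total). The printed per-category counts
(284 missing-ABP, 9 missing-ECG, 22 missing-PPG, 114 abnormal-ABP,
21 abnormal-ECG, 7 abnormal-PPG, 121 good) are treated as authoritative;
the following typographic artifacts in the printed ID lists were resolved
so the lists match those counts:

1. Abnormal-ABP list: the run-together token `s29199s1004` was split into
   `s29199` and `s1004` (raw list length 113 vs. the stated 114; splitting
   restores the count).
2. Included list: the unprefixed token `44496`, printed inside a run of
   `a`-prefixed IDs, was normalized to `a44496`.
3. `s07614` is printed in both the abnormal-ABP list and the included
   list. The per-subject results table lists subject 7614 in the included
   cohort, so the included occurrence is taken as genuine. The true
   identity of the abnormal-ABP entry cannot be recovered from the text;
   it is retained under the placeholder ID `s07614-dup` so that the
   printed per-category counts and the one-category-per-record invariant
   both hold. Analyses keyed by real record IDs should ignore this
   placeholder.

No other edits were made; IDs are otherwise verbatim.
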