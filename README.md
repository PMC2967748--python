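# ademiner

Mining **multi-item adverse-drug-event associations** from spontaneous
reporting system (SRS) data.

Standard pharmacovigilance screens one drug against one adverse event at a
time. Associations involving several drugs and/or several events — the kind
that flag possible drug–drug interactions — are rarely mined because the
candidate space explodes (2 drugs + 3 events over 10,000-item vocabularies
is already ~10<sup>20</sup> combinations). `ademiner` makes this tractable
with a typed, constrained Apriori miner and screens the result with a
disproportionality measure instead of confidence.

For a rule *A → B* (*A* a set of drugs, *B* a set of adverse events) over
*N* reports, with *S(·)* the number of reports containing an itemset:

* support *S(A∪B)* — how often the full combination is reported;
* confidence *C(A→B) = S(A∪B)/S(A)* ≈ Pr(*B* | *A*) (reported, never used
  for screening);
* **relative reporting ratio** *RR = S(A∪B)·N / (S(A)·S(B))* — observed
  joint frequency over the frequency expected under independence; RR = 1 is
  independence, RR > 1 a positive association.

The miner generates frequent itemsets level-wise with downward-closure
pruning and posting-list (inverted-index) support counting, emits exactly
one rule per *mixed* frequent itemset (drug part → event part), screens at
support ≥ 50 and RR ≥ 2 by default, keeps multi-item rules (≥ 3 items), and
ranks by RR. Everything is deterministic: same input + config ⇒
byte-identical output.

The package is for pharmacoepidemiologists and method developers: it reads a
simple transactions format and an AERS-style `$`-delimited quarterly ASCII
dialect, normalizes free-text drug names against a user-supplied
brand→generic table, and ships a synthetic SRS generator with planted ground
truth so the whole pipeline is testable without any data download. Mined
rules are *hypotheses for expert review*, not established adverse events.

## Worked example

Four reports, two drugs of interest:

```sh
$ cat toy.jsonl
{"id": "R1", "drugs": ["warfarin", "aspirin"], "events": ["bleeding"], "outcomes": ["HO"]}
{"id": "R2", "drugs": ["warfarin", "aspirin"], "events": ["bleeding"], "outcomes": ["DE"]}
{"id": "R3", "drugs": ["warfarin"], "events": ["rash"], "outcomes": ["HO"]}
{"id": "R4", "drugs": ["aspirin"], "events": ["bleeding"], "outcomes": ["HO"]}

$ ademiner --quiet mine --input toy.jsonl -o rules.tsv \
    --min-support 2 --min-rr 1.0 --no-serious-filter --min-drugs 0
$ cat rules.tsv
antecedent	consequent	support	support_antecedent	support_consequent	n_reports	confidence	rr
ASPIRIN,WARFARIN	BLEEDING	2	2	3	4	1	1.333
```

Reading the one surviving rule: {aspirin, warfarin} → bleeding appears in 2
of 4 reports (support 2); both reports containing the drug pair report
bleeding (confidence 1); and the pair+event combination is reported 1.33×
more often than expected if the drug pair and the event were independent
(RR = 2·4 / (2·3) = 1.333). The single-drug rules mined alongside
(aspirin → bleeding, RR 0.89; warfarin → bleeding, RR 1.33) are dropped by
the multi-item filter or the RR ≥ 1 screen.

The same pipeline runs end-to-end on synthetic data with known truth:

```sh
$ ademiner --quiet simulate --n-reports 20000 --seed 7 --planted -o syn.jsonl --truth-out truth.json
wrote 20000 reports to syn.jsonl
$ ademiner --quiet mine --input syn.jsonl -o syn_rules.tsv --min-drugs 0
$ head -2 syn_rules.tsv
antecedent	consequent	support	support_antecedent	support_consequent	n_reports	confidence	rr
DRUG_0090,DRUG_0100	EVENT_0001,EVENT_0070,EVENT_0080	51	140	51	20000	0.3643	142.9
```

All five planted multi-item associations survive the default (50, 2) screen
and rank at the top by RR; `truth.json` holds their realized supports for
comparison. `ademiner describe --input ...` prints corpus statistics
(reports, items per report, multi-drug fractions) without mining, and
`ademiner normalize` dry-runs the drug-name mapping.

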