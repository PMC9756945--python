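"""Build training labels from trio inheritance.

Runs the candidate filters (rare, >= 2 targets, autosomal, outside segdups),
merges multi-caller calls by depth contrast, and labels child calls:
inherited -> rare DEL/DUP, refined Mendelian errors -> artifact.
"""

from collections import Counter

import cnvconfirm as cc

cohort = cc.simulate_cohort(cc.SimulationConfig(n_families=50, seed=2))
normalized, _ = cc.gc_normalize(cohort.matrix)
by_caller = cc.emit_caller_calls(cohort)
all_calls = [c for calls in by_caller.values() for c in calls]
print(f"raw candidate calls from {len(by_caller)} callers: {len(all_calls)}")

filtered = cc.filter_candidate_calls(all_calls, cohort.segdups)
print(f"after rare/multi-target/autosome/segdup filters: {len(filtered)}")

merged = cc.merge_caller_calls(filtered, normalized)
print(f"after multi-caller merging: {len(merged)}")

by_sample = {}
for c in merged:
    by_sample.setdefault(c.sample_id, []).append(c)
labeled = cc.label_cohort(by_sample, cohort.pedigree, cohort.parent_nq)
counts = Counter(l.label for l in labeled)
print(f"labeled training calls: {dict(counts)}")
print("unlabeled child calls (ambiguous/possible de novo) are excluded from training")

train, val, test = cc.split_dataset(labeled, seed=0)
print(f"split 60/20/20 -> {len(train)}/{len(val)}/{len(test)}")
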