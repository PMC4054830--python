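"""Chou-form metrics on whole-protein scan confusion counts.

Recomputes the four published human-histone scan examples from their class
totals (N+, N-) and miss counts (N-+, N+-), plus the random-prediction
limit case.
"""

from methylsite import ChouCounts, chou_metrics

cases = [
    ("P62805 Arg scan", ChouCounts(n_pos=1, n_neg=13, miss_pos=0, miss_neg=1)),
    ("P68431 Arg scan", ChouCounts(n_pos=3, n_neg=15, miss_pos=0, miss_neg=0)),
    ("P62805 Lys scan", ChouCounts(n_pos=1, n_neg=10, miss_pos=0, miss_neg=2)),
    ("P68431 Lys scan", ChouCounts(n_pos=11, n_neg=2, miss_pos=0, miss_neg=1)),
    ("half of each class wrong", ChouCounts(10, 20, 5, 10)),
]

for name, counts in cases:
    m = chou_metrics(counts)
    print(f"{name}: N+={counts.n_pos} N-={counts.n_neg} "
          f"N-+={counts.miss_pos} N+-={counts.miss_neg} -> "
          f"Sn={m.sn:.2f} Sp={m.sp:.2f} Acc={m.acc:.2f} MCC={m.mcc:.2f}")

print()
print("Sn = 1 - N-+/N+ and Sp = 1 - N+-/N- make the error structure")
print("directly readable; MCC balances both error types, hitting 0 exactly")
print("when half of each class is mispredicted (random-level prediction).")
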