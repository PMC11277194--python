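"""The half-credit ordinal accuracy and its companion metrics.

Forecast levels one step off the truth are plausible survey error, so
AC = (M + 0.5 D) / N counts them at half weight.  The example scores a
small forecast by hand and also shows the binary (outbreak vs none)
confusion metrics.
"""

from gepcast.metrics import (
    confusion_from_levels,
    count_match_levels,
    evaluation_report,
    level_accuracy,
    mcc,
)

truth = [1, 1, 2, 3, 2, 1, 3, 2, 2, 1]
pred = [1, 2, 2, 2, 2, 1, 3, 1, 2, 1]

counts = count_match_levels(truth, pred)
print(f"N={counts.total}, exact matches M={counts.exact_matches}, "
      f"one-level misses D={counts.off_by_one}")
print(f"AC = (M + 0.5 D)/N = {level_accuracy(counts):.2f}%")

conf = confusion_from_levels(truth, pred)  # level >= 2 counts as outbreak
print(f"outbreak-vs-none confusion: TP={conf.tp} FP={conf.fp} "
      f"FN={conf.fn} TN={conf.tn}, MCC={mcc(conf):.3f}")

report = evaluation_report(truth, [float(p) for p in pred], pred)
print(f"full report keys: {sorted(report)}")
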