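"""Recompute sensitivity, specificity, Gmean and the Sn/Sp F-score from
published confusion-matrix counts for a diabetes classifier benchmark."""

from chaoelm.metrics import (
    ConfusionCounts, accuracy, gmean, round4, sensitivity, sp_sn_fscore, specificity,
)

# plain ELM at 10 hidden neurons: 144 true positives, 21 false negatives,
# 20 false positives, 45 true negatives on a 230-sample test split
counts = ConfusionCounts(tp=144, fn=21, fp=20, tn=45)
sn, sp = sensitivity(counts), specificity(counts)
print(f"sensitivity {round4(sn)}   specificity {round4(sp)}")
print(f"gmean       {round4(gmean(sn, sp))}   fscore      {round4(sp_sn_fscore(sn, sp))}")
print(f"accuracy    {round4(accuracy(counts))}")
# Gmean is sqrt(Sn*Sp); the F-score here is the harmonic mean of Sn and Sp
# (not the precision/recall F1), the convention used in this benchmark line.
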