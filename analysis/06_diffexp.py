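"""Negative-binomial fold-change tests: total mRNA 7 h vs 2 h, unlabeled vs
total at 7 h (the masked-decay contrast), and miR-430-LNA vs control-LNA
for each mRNA fraction.
"""

from pathlib import Path

import pandas as pd

from slam_mzt.pipeline import FILES, RunConfig, stage_diffexp

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main():
    cfg = RunConfig.from_yaml(RUN_DIR / FILES["config"])
    stage_diffexp(cfg, RUN_DIR)
    de = pd.read_csv(RUN_DIR / FILES["de_total_7v2"], index_col="gene_id")
    sig = de[(de["padj"] <= 0.05)]
    print(f"total mRNA 7 h vs 2 h: {len(de)} genes tested, "
          f"{(sig['log2fc'] < 0).sum()} significantly down, "
          f"{(sig['log2fc'] > 0).sum()} significantly up (padj <= 0.05)")
    lna = pd.read_csv(RUN_DIR / FILES["de_lna"])
    for fraction, grp in lna.groupby("fraction"):
        n_up = ((grp["padj"] <= 0.05) & (grp["log2fc"] > 0)).sum()
        print(f"LNA-430 vs control, {fraction}: {n_up} genes up at padj <= 0.05")


if __name__ == "__main__":
    main()
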