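"""Find maternal-zygotic genes whose maternal decay is masked by zygotic
synthesis: flat total mRNA between 2 and 7 h but a significant drop of the
unlabeled (maternal) fraction against total at 7 h; split the flagged set
by miR-430 site presence.
"""

from pathlib import Path

import pandas as pd

from slam_mzt.pipeline import FILES, RunConfig, stage_masked_decay

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main():
    cfg = RunConfig.from_yaml(RUN_DIR / FILES["config"])
    info = stage_masked_decay(cfg, RUN_DIR)
    out = pd.read_csv(RUN_DIR / FILES["masked_decay"], index_col="gene_id")
    flagged = out[out["masked_decay"]]
    print(f"masked-decay genes: {info['n_masked_decay']} "
          f"({info['n_masked_decay_targets']} with a miR-430 site)")
    if len(flagged):
        print("median total log2FC(7v2) of flagged genes: "
              f"{flagged['total_log2fc_7v2'].median():.2f}; "
              f"median unlabeled-vs-total log2FC: {flagged['tvu_log2fc'].median():.2f}")


if __name__ == "__main__":
    main()
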