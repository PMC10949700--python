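"""Drop lowly expressed genes, derive ERCC spike-in scaling factors, and
write CPM matrices for the total, labeled and unlabeled fractions (all
scaled by the total fraction's effective library sizes).
"""

from pathlib import Path

import pandas as pd

from slam_mzt.pipeline import FILES, RunConfig, stage_normalize

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main():
    cfg = RunConfig.from_yaml(RUN_DIR / FILES["config"])
    info = stage_normalize(cfg, RUN_DIR)
    factors = pd.read_csv(RUN_DIR / FILES["factors"], index_col=0)
    print(f"kept {info['n_genes_kept']} genes after the low-expression filter")
    print("spike-in scaling factors: "
          f"min {factors['scaling_factor'].min():.3f}, "
          f"median {factors['scaling_factor'].median():.3f}, "
          f"max {factors['scaling_factor'].max():.3f}")


if __name__ == "__main__":
    main()
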