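"""Scan every gene's 3'UTR for miR-430 seed matches (6mer GCACTT up to the
8mer AGCACTTA, longest-site-wins overlap resolution) and label each gene's
target status against the known-target prior list.
"""

from pathlib import Path

import pandas as pd

from slam_mzt.pipeline import FILES, RunConfig, stage_sites

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main():
    cfg = RunConfig.from_yaml(RUN_DIR / FILES["config"])
    info = stage_sites(cfg, RUN_DIR)
    table = pd.read_csv(RUN_DIR / FILES["site_counts"], index_col="gene_id")
    print(f"{info['n_genes_with_site']} genes carry at least one miR-430 site")
    print(table[["6mer", "s6mer-O", "7mer-A1", "7mer-M8", "8mer"]].sum().to_string())
    print(table["target_status"].value_counts().to_string())


if __name__ == "__main__":
    main()
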