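"""Score the zygotic component of every gene (ZCS = labeled/total CPM),
assign maternal / maternal-zygotic / zygotic classes, date each gene's
transcriptional activation hour (>1 labeled CPM in >=2 replicates), and
label post-activation labeled-CPM trajectories (up/flat/down).
"""

from pathlib import Path

import pandas as pd

from slam_mzt.pipeline import FILES, RunConfig, stage_classify

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main():
    cfg = RunConfig.from_yaml(RUN_DIR / FILES["config"])
    stage_classify(cfg, RUN_DIR)
    cls = pd.read_csv(RUN_DIR / FILES["classification"], index_col="gene_id")
    print("MZT classes:")
    print(cls["mzt_class"].value_counts().to_string())
    act = cls["activation_hour"].dropna()
    print("hourly activation groups (genes first exceeding 1 labeled CPM):")
    print(act.value_counts().sort_index().to_string())
    flat = cls["trajectory"].str.split(",").explode()
    flat = flat[flat != ""]
    print("post-activation interval labels:")
    print(flat.value_counts().to_string())


if __name__ == "__main__":
    main()
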