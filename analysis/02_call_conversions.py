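"""Call the T>C SNP mask from pooled control libraries (transcription-off +
non-injected), then classify every read with the >=2-unmasked-conversions
rule and write the tri-layer counts table (total / labeled per sample).
"""

from pathlib import Path

import pandas as pd

from slam_mzt.pipeline import FILES, RunConfig, stage_count, stage_snps

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main():
    cfg = RunConfig.from_yaml(RUN_DIR / FILES["config"])
    snp_info = stage_snps(cfg, RUN_DIR)
    print(f"SNP mask: {snp_info['n_snp_positions']} positions "
          f"from {snp_info['n_control_samples']} control libraries "
          f"(-f {cfg.thresholds.snp_min_fraction} -c {cfg.thresholds.snp_min_coverage})")
    count_info = stage_count(cfg, RUN_DIR)
    counts = pd.read_csv(RUN_DIR / FILES["counts"])
    total_cols = [c for c in counts.columns if c.startswith("total_")]
    labeled_cols = [c for c in counts.columns if c.startswith("labeled_")]
    frac = counts[labeled_cols].to_numpy().sum() / counts[total_cols].to_numpy().sum()
    print(f"counts table: {count_info['n_rows']} features x {count_info['n_samples']} samples; "
          f"overall labeled-read fraction {frac:.3f}")


if __name__ == "__main__":
    main()
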