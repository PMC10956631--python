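"""Generate the study-scale synthetic dataset.

Writes paired BS/oxBS beta matrices, CpG/gene annotation, covariates,
expression and the planted-truth tables, and reports what was planted.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import OUT_DIR, run_through  # noqa: E402


def main():
    state = run_through("simulate")
    d = state.data
    truth = d.truth
    print(f"wrote {OUT_DIR}: {len(d.cpgs)} CpGs x {d.betas.bs.shape[1]} "
          f"samples, {len(d.genes)} genes")
    print(f"true 5hmC grand mean: {100 * d.truth.hmc_true.to_numpy().mean():.2f}%")
    print(f"realized systematic CpGs: {int(truth.cpgs['systematic'].sum())} "
          f"({100 * truth.cpgs['systematic'].mean():.1f}%)")
    print(f"planted cis effects: {len(truth.pairs)} pairs "
          f"(beta1 = {truth.pairs['beta1'].iloc[0]:.2f} per M-value unit)")
    print(f"planted DHMRs: {len(truth.regions)} regions of "
          f"{truth.regions['n_cpgs'].iloc[0]} CpGs")


if __name__ == "__main__":
    main()
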