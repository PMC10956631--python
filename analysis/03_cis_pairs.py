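"""Build the cis CpG-gene pair universe: CpGs inside a gene or within 1 Mb
upstream of its TSS / 1 Mb downstream of its TTS.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import run_through  # noqa: E402


def main():
    state = run_through("annotate")
    pairs = state.cis_pairs
    print(f"cis pairs: {len(pairs)} "
          f"({pairs['cpg_id'].nunique()} CpGs x {pairs['gene_id'].nunique()} genes)")
    print("zone breakdown:", pairs["zone"].value_counts().to_dict())
    per_gene = pairs.groupby("gene_id").size()
    print(f"cis CpGs per gene: median {int(per_gene.median())}, "
          f"range {int(per_gene.min())}-{int(per_gene.max())}")


if __name__ == "__main__":
    main()
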