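"""Enrichment of systematic 5hmC across CGI classes and chromatin states
(Fisher's exact OR with Woolf 95% CI) plus the repeated-measures ANOVA of
5hmC across chromatin states.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import run_through  # noqa: E402


def main():
    state = run_through("enrich")
    tables = state.enrichment_tables["tables"]
    summary = state.enrichment_tables["summary"]
    print("systematic-5hmC enrichment by CGI class (OR [95% CI], p):")
    for r in tables["cgi"].itertuples(index=False):
        print(f"  {r.category:>9s}: {r.odds_ratio:5.2f} "
              f"[{r.ci_low:.2f}, {r.ci_high:.2f}]  p={r.p_value:.3g}")
    print("by chromatin state:")
    for r in tables["chromhmm"].itertuples(index=False):
        print(f"  {r.category:>22s}: {r.odds_ratio:5.2f} "
              f"[{r.ci_low:.2f}, {r.ci_high:.2f}]  p={r.p_value:.3g}")
    print(f"ANOVA of 5hmC across chromatin states: "
          f"F={summary['chromhmm_anova_F']:.1f}, "
          f"p={summary['chromhmm_anova_p']:.3g}")
    print(f"grand mean 5hmC {summary['grand_mean_pct']:.2f}%; systematic "
          f"{summary['n_systematic']} ({summary['pct_systematic']:.1f}%) "
          f"with mean {summary['systematic_mean_pct']:.2f}%")


if __name__ == "__main__":
    main()
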