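"""Rank regulators by mean activity-MRSS correlation within each subset.

For the fibroproliferative and inflammatory subsets, computes per-cohort
Pearson correlations between activity and MRSS, averages across cohorts,
ranks in decreasing order, and flags the top and bottom of the ranking as
clinically relevant regulators.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SIM_DIR, cohort_names  # noqa: E402

from regact.clinical_correlation import aggregate_rank, correlate_mrss  # noqa: E402
from regact.io_formats import read_clinical, read_scores  # noqa: E402

TOP_K = 15  # top/bottom flag size for this 60-regulator study


def main() -> None:
    truth = json.loads((SIM_DIR / "truth.json").read_text())
    drivers = set(truth["mrss_drivers"])
    for subset in ("fibroproliferative", "inflammatory"):
        tables = {}
        for name in cohort_names():
            am = read_scores(RESULTS / f"activity_{name}.tsv")
            ct = read_clinical(SIM_DIR / f"clinical_{name}.tsv")
            tables[name] = correlate_mrss(am, ct, subset)
        ranking = aggregate_rank(tables, method="mean", k=TOP_K)
        ranking.table.to_csv(RESULTS / f"ranking_{subset}.tsv", sep="\t")
        top = ranking.flagged("top50")
        hit = drivers & set(top)
        print(
            f"{subset}: top-{TOP_K} flag contains {len(hit)}/{len(drivers)} "
            f"planted MRSS drivers; best aggregate PCC "
            f"{ranking.table['aggregate'].iloc[0]:+.3f}"
        )


if __name__ == "__main__":
    main()
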