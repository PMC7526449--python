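"""Score per-sample regulator activity in every cohort.

Reads the simulated cohorts from results/sim/, quantile-normalizes each
expression matrix (median-centering the single-channel cohort), computes
permutation-normalized activity scores and writes them under results/.
"""

import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import (  # noqa: E402
    MASTER_SEED,
    N_PERM_BASE,
    RESULTS,
    SIM_DIR,
    cohort_names,
)

from regact.base_scoring import base_activity, normalize_expression  # noqa: E402
from regact.io_formats import (  # noqa: E402
    preprocess_probes,
    read_expression,
    read_gmt,
    write_scores,
)


def main() -> None:
    sets = read_gmt(SIM_DIR / "sets.gmt")
    for i, name in enumerate(cohort_names()):
        dialect = (SIM_DIR / f"dialect_{name}.txt").read_text().strip()
        pm = read_expression(SIM_DIR / f"expr_{name}.tsv", dialect=dialect)
        em = normalize_expression(preprocess_probes(pm))
        t0 = time.time()
        am = base_activity(em, sets, n_perm=N_PERM_BASE, seed=MASTER_SEED + i)
        write_scores(am, RESULTS / f"activity_{name}.tsv")
        print(
            f"{name} ({dialect}): scored {am.scores.shape[0]} regulators x "
            f"{am.scores.shape[1]} samples in {time.time() - t0:.1f}s"
        )


if __name__ == "__main__":
    main()
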