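#!/usr/bin/env python
"""Marker prognosis on the synthetic cohort: cut-points, KM, ORs, AUC.

Splits the 594-patient synthetic cohort into a training half (cut-point
learned by maximizing sensitivity x specificity per endpoint) and a test
half (KM curves, log-rank, univariable and covariate-adjusted odds ratios,
AUC with DeLong CIs).  Writes results/prognosis.json and the KM step
functions as TSV.
"""
import json
from pathlib import Path

import numpy as np

from erlnc.pipeline import _json_default
from erlnc.prognosis import SurvivalCohort, evaluate_marker

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"
SEED = 13


def main() -> None:
    cohort = SurvivalCohort.from_tsv(STUDY / "cohort.tsv")
    rng = np.random.default_rng(SEED)
    n = len(cohort)
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=n // 2, replace=False)] = True
    train = SurvivalCohort(cohort.table[mask].reset_index(drop=True))
    test = SurvivalCohort(cohort.table[~mask].reset_index(drop=True))
    report = evaluate_marker(train, test, covariates=cohort.covariates)

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "prognosis.json").write_text(
        json.dumps(report, indent=1, default=_json_default))
    for ep in ("bcr", "met"):
        for arm in ("high", "low"):
            report[ep][f"km_{arm}"].to_frame().to_csv(
                RESULTS / f"km_{ep}_{arm}.tsv", sep="\t", index=False,
                float_format="%.6g")

    print(f"cohort n={n}: train {int(mask.sum())}, test {n - int(mask.sum())}")
    for ep in ("bcr", "met", "pcsm", "gs7"):
        e = report[ep]
        line = (f"{ep.upper():>4}: cut {e['cutpoint'].cut:.2f} "
                f"(sens {e['cutpoint'].sensitivity:.2f} x "
                f"spec {e['cutpoint'].specificity:.2f}); "
                f"OR {e['univariable']['or']:.2f} "
                f"[{e['univariable']['ci_low']:.2f}, {e['univariable']['ci_high']:.2f}]; "
                f"AUC {e['auc']['auc']:.3f}")
        if "logrank" in e:
            line += f"; log-rank p {e['logrank']['p']:.3g}"
        print(line)
    print(f"wrote {RESULTS / 'prognosis.json'} and KM step functions")


if __name__ == "__main__":
    main()
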