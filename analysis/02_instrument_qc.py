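"""Instrument QC for every leg: selection, clumping, F filter, harmonization.

Reads the simulated GWAS tables from scratch/sim/, applies the
microbiota-exposure thresholds (p < 1e-5) to taxa and the genome-wide
threshold (p < 5e-8) to the disease exposure, and writes per-leg instrument
counts at each QC stage to results/instrument_qc.tsv.
"""

from pathlib import Path

import pandas as pd

from trimr import (SelectionConfig, drop_palindromic, f_filter, harmonize,
                   maf_filter, read_sumstats, select_by_p, write_results)

SCRATCH = Path("scratch/sim")
RESULTS = Path("results")


def qc_counts(exposure, outcome, cfg, n_exp):
    stages = {"candidates": len(exposure)}
    sel = select_by_p(exposure, cfg.p_threshold)
    stages["p_filter"] = len(sel)
    sel = f_filter(sel, cfg.f_min, n_fallback=n_exp)
    stages["f_filter"] = len(sel)
    sel = drop_palindromic(sel)
    stages["palindromic"] = len(sel)
    sel = maf_filter(sel, cfg.maf_min)
    stages["maf"] = len(sel)
    hs = harmonize(sel, outcome)
    stages["harmonized"] = len(hs)
    return stages


def main() -> None:
    micro_cfg = SelectionConfig()                      # p < 1e-5
    disease_cfg = SelectionConfig.for_disease_exposure()  # p < 5e-8
    rows = []

    ibd = read_sumstats(SCRATCH / "ibd_exposure.tsv", "ibd")
    for path in sorted(SCRATCH.glob("leg1_*.tsv")) + sorted(SCRATCH.glob("leg2_*.tsv")):
        outcome = read_sumstats(path)
        rows.append({"leg": path.stem, "exposure": "ibd",
                     **qc_counts(ibd, outcome, disease_cfg, 65_642)})

    for path in sorted(SCRATCH.glob("leg3_exposure_*.tsv")):
        taxon = path.stem.removeprefix("leg3_exposure_")
        exposure = read_sumstats(path, taxon)
        outcome = read_sumstats(SCRATCH / f"leg3_outcome_{taxon}.tsv")
        rows.append({"leg": f"leg3_{taxon}", "exposure": taxon,
                     **qc_counts(exposure, outcome, micro_cfg, 18_340)})

    table = pd.DataFrame(rows)
    write_results(table, RESULTS / "instrument_qc.tsv")
    print(table.to_string(index=False))
    print(f"\nwrote {RESULTS}/instrument_qc.tsv")


if __name__ == "__main__":
    main()
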