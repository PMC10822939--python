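"""Simulate the synthetic three-leg MR study.

Builds the study inputs with known ground truth:

* a 211-taxon bacterial taxonomy panel with 15 unnamed traits,
* leg 1 (disease exposure -> extraintestinal outcomes): two outcome GWAS
  driven by a true causal effect of the disease,
* leg 2 (disease -> taxa): eight taxon abundance GWAS, three causally
  downstream of the disease,
* leg 3 (taxa -> outcome): the same eight taxa as exposures of an
  extraintestinal outcome, with a mix of true effects, a null majority,
  one directionally pleiotropic pair and one outlier-contaminated pair.

GWAS tables go to scratch/sim/ (regenerable); the truth ledger and the
filtered taxonomy go to results/.
"""

import json
from pathlib import Path

from trimr import SimConfig, filter_named_taxa, make_taxonomy_fixture, simulate_pair, write_results

SCRATCH = Path("scratch/sim")
RESULTS = Path("results")
SEED = 20260928

# (label, rank, theta, extras) for the taxa -> outcome leg
TAXA_LEGS = [
    ("genus_Odoribacter", "genus", -0.45, {}),
    ("genus_Bilophila", "genus", 0.35, {}),
    ("family_Rikenellaceae", "family", -0.40, {}),
    ("genus_Dorea", "genus", 0.0, {}),
    ("genus_Holdemanella", "genus", 0.0, {}),
    ("order_Desulfovibrionales", "order", 0.0, {"pleio_mu": 0.02, "pleio_tau": 0.01}),
    ("class_Deltaproteobacteria", "class", 0.30, {"pleio_tau": 0.02, "outlier_frac": 0.05}),
    ("phylum_Bacteroidetes", "phylum", 0.0, {}),
]

# disease -> taxa: which taxa are truly downstream of the disease
DISEASE_TO_TAXA = {"genus_Odoribacter": 0.03, "genus_Bilophila": 0.025,
                   "family_Rikenellaceae": 0.0, "genus_Dorea": 0.0}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    truth_ledger = {}

    taxonomy = make_taxonomy_fixture(n_taxa=211, n_unknown=15, seed=SEED)
    taxonomy.to_csv(SCRATCH / "taxonomy.tsv", sep="\t", index=False)
    named = filter_named_taxa(taxonomy)
    print(f"taxonomy panel: {len(taxonomy)} taxa, {len(taxonomy) - len(named)} unnamed, "
          f"{len(named)} analysable")

    # one disease exposure GWAS shared by legs 1 and 2 (same seed, distinct
    # outcome streams), as in a real study where a single IBD GWAS supplies
    # the instruments for every downstream outcome
    ibd_seed = SEED + 100

    # leg 1: disease exposure (instruments at genome-wide significance) -> outcomes
    for i, (outcome, theta) in enumerate([("eim_psoriatic_arthropathies", 0.24),
                                          ("eim_iridocyclitis", 0.20)]):
        cfg = SimConfig(n_snps=80, n_exp=65_642, n_out=350_000, theta=theta,
                        seed=ibd_seed, outcome_seed=SEED + 110 + i)
        exp, out, truth = simulate_pair(cfg)
        write_results(exp, SCRATCH / "ibd_exposure.tsv")  # identical across iterations
        write_results(out, SCRATCH / f"leg1_{outcome}.tsv")
        truth_ledger[f"ibd->{outcome}"] = {"theta": truth.theta, "seed": cfg.seed}

    # leg 2: disease -> taxon abundance
    for i, (taxon, theta) in enumerate(DISEASE_TO_TAXA.items()):
        cfg = SimConfig(n_snps=80, n_exp=65_642, n_out=18_340, theta=theta,
                        seed=ibd_seed, outcome_seed=SEED + 120 + i)
        exp, out, truth = simulate_pair(cfg)
        write_results(out, SCRATCH / f"leg2_{taxon}.tsv")
        truth_ledger[f"ibd->{taxon}"] = {"theta": truth.theta, "seed": cfg.seed}

    # leg 3: taxon abundance (locus-wide instruments) -> outcome
    for i, (taxon, rank, theta, extras) in enumerate(TAXA_LEGS):
        cfg = SimConfig(n_snps=60, n_exp=18_340, n_out=350_000, theta=theta,
                        seed=SEED + 300 + i, **extras)
        exp, out, truth = simulate_pair(cfg)
        write_results(exp, SCRATCH / f"leg3_exposure_{taxon}.tsv")
        write_results(out, SCRATCH / f"leg3_outcome_{taxon}.tsv")
        truth_ledger[f"{taxon}->eim"] = {"theta": truth.theta, "rank": rank,
                                         "seed": cfg.seed, **extras}

    with open(RESULTS / "sim_truth.json", "w") as fh:
        json.dump(truth_ledger, fh, indent=1)
    n_files = len(list(SCRATCH.glob("*.tsv")))
    print(f"wrote {n_files} summary-statistic tables to {SCRATCH}/ "
          f"and the truth ledger to {RESULTS}/sim_truth.json")


if __name__ == "__main__":
    main()
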