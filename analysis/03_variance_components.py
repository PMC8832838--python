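#!/usr/bin/env python
"""Partition the phenotypic variance of male crossover counts.

Fits the sequence of mixed models the study design prescribes — base
(autosomal polygenic + permanent environment), + X-linked effect,
+ Y-lineage effect, and both — compares them by likelihood-ratio tests,
and reports heritability, repeatability and the X share of the genetic
variance with sampling-based SDs. Writes results/vc/variance_components.json.
"""

import json
import os

from xgrr import io, pedrel, vc

IN_DIR = "results/cohort"
OUT_DIR = "results/vc"


def main():
    ped = io.read_pedigree(f"{IN_DIR}/pedigree.tsv")
    records = io.read_records(f"{IN_DIR}/records.tsv")
    A = pedrel.autosomal_A(ped)
    S = pedrel.xlinked_S(ped)
    lin = pedrel.y_lineages(ped)
    structures = {"u": A, "s": S, "i": lin}

    fits = {}
    for label, terms in [
        ("base", ("u", "p")),
        ("with_x", ("u", "p", "s")),
        ("with_y", ("u", "p", "i")),
        ("with_xy", ("u", "p", "s", "i")),
    ]:
        fits[label] = vc.fit_reml(vc.ModelSpec(random=terms), records, structures)

    lrt_x = vc.lrt_vc(fits["with_x"], fits["base"])
    lrt_y = vc.lrt_vc(fits["with_y"], fits["base"])
    lrt_y_x = vc.lrt_vc(fits["with_xy"], fits["with_x"])
    der = vc.derived_params(fits["with_x"], seed=1)

    print("variance components (model with X term):")
    for k, v in fits["with_x"].variances.items():
        se = fits["with_x"].se(k)
        print(f"  sigma2_{k} = {v:.4f}" + ("" if se != se else f" (SE {se:.4f})"))
    print(f"LRT X effect:  stat={lrt_x[0]:.2f} p={lrt_x[1]:.2e}")
    print(f"LRT Y effect:  stat={lrt_y[0]:.2f} p={lrt_y[1]:.2e}")
    print(f"LRT Y given X: stat={lrt_y_x[0]:.2f} p={lrt_y_x[1]:.2e}")
    print(f"h2 = {100 * der.heritability:.1f}% (+/- {100 * der.heritability_sd:.1f})")
    print(f"repeatability = {100 * der.repeatability:.1f}% "
          f"(+/- {100 * der.repeatability_sd:.1f})")
    print(f"X share of genetic variance = {100 * der.x_fraction:.1f}% "
          f"(+/- {100 * der.x_fraction_sd:.1f})")

    out = {
        "models": {k: f.variances for k, f in fits.items()},
        "logliks": {k: f.loglik for k, f in fits.items()},
        "lrt": {"x": lrt_x, "y": lrt_y, "y_given_x": lrt_y_x},
        "heritability": der.heritability,
        "heritability_sd": der.heritability_sd,
        "repeatability": der.repeatability,
        "x_fraction_of_genetic": der.x_fraction,
        "x_fraction_sd": der.x_fraction_sd,
    }
    with open(f"{OUT_DIR}/variance_components.json", "w") as fh:
        json.dump(out, fh, indent=2)


if __name__ == "__main__":
    os.makedirs(OUT_DIR, exist_ok=True)
    main()
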