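"""Generate the small demonstration cohort used in the README.

Writes a binary PLINK triplet (``cohort.bed/.bim/.fam``), the matching
VCF, and a marginal Z-score table ``z.tsv`` computed from a simulated
phenotype with three causal variants, into the directory given on the
command line (default: current directory).

Run, then follow the README:

    python examples/make_example.py demo/
    cd demo
    solveblock --bed cohort --out bundle/ --m 5 --cutoff 0.5 --key-c 0.5
    ghostgwas --zfile z.tsv --bundle bundle/ --q 0.10 --seed 2025 --out hits.tsv
"""

import sys
from pathlib import Path

import pandas as pd

from knockblock import (
    BlockSpec,
    SimulationConfig,
    impute_and_standardize,
    marginal_z,
    qc_filter,
    simulate_genotypes,
    simulate_phenotype,
    write_fixtures,
)

out_dir = Path(sys.argv[1]) if len(sys.argv) > 1 else Path(".")
out_dir.mkdir(parents=True, exist_ok=True)

config = SimulationConfig(
    n=800, blocks=[BlockSpec(size=40, rho=0.5)], maf_range=(0.1, 0.5), k=4,
)
G = simulate_genotypes(config, seed=21)
paths = write_fixtures(G, out_dir, name="cohort")

Gq = qc_filter(G)
X = impute_and_standardize(Gq)
y, causal = simulate_phenotype(X, k=4, effect_sd=2.0, noise_var=1.0, seed=4)
z = marginal_z(X, y)
pd.DataFrame(
    {
        "CHR": Gq.variants["chrom"],
        "POS": Gq.variants["pos"],
        "REF": Gq.variants["ref"],
        "ALT": Gq.variants["alt"],
        "Z": z,
    }
).to_csv(out_dir / "z.tsv", sep="\t", index=False)

causal_ids = Gq.variants["id"].iloc[causal].tolist()
print(f"wrote {paths['plink_prefix']}.bed/.bim/.fam, {paths['vcf']}, z.tsv")
print(f"causal variants: {causal_ids}")
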