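"""Ready-to-edit command templates for downstream tools.

Generates (a) chunk-wise IMPUTE2 command lists with per-chunk bp bounds,
(b) EIGENSOFT parameter-file bundles for SMARTPCA / SMARTEIGENSTRAT with a
plotting script, and (c) a GenABEL-style phenotype file plus R import
script.  Bundles are pure text: identical inputs give byte-identical
output, and nothing is ever executed by this package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional


@dataclass
class TemplateBundle:
    """Named text files plus the placeholder tokens the user must edit."""

    files: dict = field(default_factory=dict)        # name -> text
    placeholders: list = field(default_factory=list)

    def write(self, out_dir: str) -> dict:
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for name, text in self.files.items():
            path = os.path.join(out_dir, name)
            with open(path, "w", newline="\n") as fh:
                fh.write(text)
            paths[name] = path
        return paths


def impute_commands(chunks: list, file_stem: str,
                    ref_placeholders: Optional[dict] = None,
                    interpreter: str = "#!/bin/sh") -> TemplateBundle:
    """One IMPUTE2 command per chunk, a chunk-limits table and a batch script.

    ``chunks`` are inclusive (lower, upper) bp bounds (see
    :func:`genoconv.manage.make_chunks`).  Reference-panel paths are emitted
    as placeholder tokens to edit; IMPUTE2 flag spelling (-h/-l/-m, -int) is
    used.
    """
    if not chunks:
        raise ValueError("chunks must be non-empty")
    ref = {"hap": "__REF_HAP__", "legend": "__REF_LEGEND__", "map": "__REF_MAP__"}
    if ref_placeholders:
        ref.update(ref_placeholders)

    limits = ["chunk\tlower_bp\tupper_bp"]
    commands = []
    for k, (lo, hi) in enumerate(chunks, 1):
        limits.append(f"{k}\t{lo}\t{hi}")
        commands.append(
            f"impute2 -g {file_stem}.gens -sample_g {file_stem}.sample "
            f"-h {ref['hap']} -l {ref['legend']} -m {ref['map']} "
            f"-int {lo} {hi} -o {file_stem}_chunk{k}.impute2"
        )
    script = "\n".join([interpreter, ""] + commands) + "\n"
    bundle = TemplateBundle(
        files={
            f"{file_stem}_chunk_limits.txt": "\n".join(limits) + "\n",
            f"{file_stem}_impute_commands.txt": "\n".join(commands) + "\n",
            f"{file_stem}_run_impute.sh": script,
        },
        placeholders=sorted(set(ref.values())),
    )
    return bundle


def eigensoft_bundle(file_stem: str, labeled: bool = False) -> TemplateBundle:
    """Parameter files and scripts around an already-rendered EIGENSOFT
    geno/snp/ind triple: SMARTPCA par file, SMARTEIGENSTRAT par file, an R
    script plotting the first two principal components, and a batch script
    chaining smartpca, smarteigenstrat and twstats."""
    par_pca = (
        f"genotypename: {file_stem}.geno\n"
        f"snpname: {file_stem}.snp\n"
        f"indivname: {file_stem}.ind\n"
        f"evecoutname: {file_stem}.evec\n"
        f"evaloutname: {file_stem}.eval\n"
        "numoutevec: 10\n"
        "numoutlieriter: 5\n"
    )
    par_strat = (
        f"genotypename: {file_stem}.geno\n"
        f"snpname: {file_stem}.snp\n"
        f"indivname: {file_stem}.ind\n"
        f"pcaname: {file_stem}.evec\n"
        f"outputname: {file_stem}.chisq\n"
        "numpc: 10\n"
    )
    color = "labels" if labeled else '"black"'
    r_script = (
        f'evec <- read.table("{file_stem}.evec", skip = 1)\n'
        "names(evec)[1:3] <- c(\"id\", \"PC1\", \"PC2\")\n"
        "labels <- factor(evec[[ncol(evec)]])\n"
        f'pdf("{file_stem}_pca.pdf")\n'
        f"plot(evec$PC1, evec$PC2, col = {color}, xlab = \"PC1\", ylab = \"PC2\")\n"
        "dev.off()\n"
        "# reformat the smartpca evec output for smarteigenstrat\n"
        f'write.table(evec, "{file_stem}.pca", quote = FALSE,'
        " row.names = FALSE, col.names = FALSE)\n"
    )
    batch = (
        "#!/bin/sh\n"
        "\n"
        f"smartpca -p {file_stem}_smartpca.par > {file_stem}_smartpca.log\n"
        f"smarteigenstrat -p {file_stem}_smarteigenstrat.par > {file_stem}_strat.log\n"
        f"Rscript {file_stem}_pca_plot.R\n"
        f"twstats -t twtable -i {file_stem}.eval -o {file_stem}.tw\n"
    )
    return TemplateBundle(files={
        f"{file_stem}_smartpca.par": par_pca,
        f"{file_stem}_smarteigenstrat.par": par_strat,
        f"{file_stem}_pca_plot.R": r_script,
        f"{file_stem}_run_eigensoft.sh": batch,
    })


def genabel_bundle(file_stem: str, samples: list, covars=None) -> TemplateBundle:
    """Phenotype table (id, sex, phenotype, covariates; tab-separated with
    header) plus an R script importing the rendered ped/map into GenABEL."""
    names = list(covars.names) if covars is not None and covars.names else []
    if covars is not None and names:
        by_key = {(str(r["fid"]), str(r["iid"])): [str(r[n]) for n in names]
                  for _, r in covars.data.iterrows()}
    else:
        by_key = {}
    lines = ["\t".join(["id", "sex", "pheno"] + names)]
    for s in samples:
        vals = by_key.get((s.fid, s.iid), ["NA"] * len(names))
        lines.append("\t".join([s.iid, str(s.sex), s.phenotype] + vals))
    pheno = "\n".join(lines) + "\n"
    r_script = (
        "library(GenABEL)\n"
        f'convert.snp.ped(pedfile = "{file_stem}.ped", mapfile = "{file_stem}.map",\n'
        f'                outfile = "{file_stem}.raw")\n'
        f'data <- load.gwaa.data(phenofile = "{file_stem}.pheno",\n'
        f'                       genofile = "{file_stem}.raw")\n'
    )
    return TemplateBundle(files={
        f"{file_stem}.pheno": pheno,
        f"{file_stem}_genabel_import.R": r_script,
    })
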