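"""Deterministic synthetic codon-alignment generator for testing and
demonstration.

The generator emulates the features of a multi-gene supermatrix that
the rest of the package manipulates: per-taxon GC3 targets (to exercise
compositional diagnostics), injected AGN/UCN serine co-occurrence sites
(with a ground-truth count, so the filter can be checked exactly),
optional misplaced gap-adjacent residues (for refinement tests), and
partial taxon overlap across genes (for concatenation tests). All
randomness flows from one integer seed; identical seeds reproduce
identical alignments byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from degenphy.alphabet import GAP
from degenphy.genetic_code import GeneticCode, build_code
from degenphy.msa import Msa


@dataclass
class FixtureTruth:
    """Ground truth recorded while generating a fixture set."""

    seed: int
    serine_cooccurrence_sites: dict[str, list[int]] = field(default_factory=dict)
    displaced_residues: dict[str, int] = field(default_factory=dict)
    gc3_targets: dict[str, float] = field(default_factory=dict)
    taxa_per_gene: dict[str, list[str]] = field(default_factory=dict)


def _sense_codons(code: GeneticCode, exclude_prefixes=("AG", "TC")) -> list[str]:
    return sorted(
        c
        for c, aa in code.codon_to_aa.items()
        if aa != "*" and c[:2] not in exclude_prefixes
    )


def _pick_codon(rng: np.random.Generator, pool: list[str], gc3_target: float) -> str:
    """Pick a codon biasing the third position toward a GC3 target."""
    want_gc = rng.random() < gc3_target / 100.0
    sub = [c for c in pool if (c[2] in "GC") == want_gc]
    pool = sub or pool
    return pool[rng.integers(len(pool))]


def make_fixture(
    n_taxa: int = 8,
    n_codons: int = 60,
    seed: int = 0,
    n_genes: int = 3,
    n_serine_sites: int = 4,
    n_displaced: int = 0,
    gc3_targets: list[float] | None = None,
    taxon_dropout: float = 0.2,
    table_id: int = 1,
) -> tuple[list[tuple[str, Msa]], FixtureTruth]:
    """Generate per-gene codon alignments with known ground truth.

    Parameters
    ----------
    n_taxa, n_codons : matrix dimensions per gene (codon sites per gene)
    seed : controls all randomness; same seed, same bytes
    n_genes : number of gene-region alignments
    n_serine_sites : AGN/UCN co-occurrence codon sites injected per gene
    n_displaced : residues pulled to the wrong side of a gap run, per gene
    gc3_targets : per-taxon third-position GC percentage targets
        (default: evenly spread between 30 and 80, emulating strong
        compositional heterogeneity across taxa)
    taxon_dropout : probability a non-anchor taxon is absent from a gene
    table_id : NCBI genetic code for codon content

    Returns the list of (gene name, Msa) and a :class:`FixtureTruth`
    with the injected counts, the oracle for filter/concat tests.
    """
    if n_taxa < 2 or n_codons < 1:
        raise ValueError("need at least 2 taxa and 1 codon site")
    rng = np.random.default_rng(seed)
    code = build_code(table_id)
    pool = _sense_codons(code)
    serine_agn = sorted(
        c for c, aa in code.codon_to_aa.items() if aa == "S" and c.startswith("AG")
    )
    serine_ucn = sorted(
        c for c, aa in code.codon_to_aa.items() if aa == "S" and c.startswith("TC")
    )
    taxa = [f"taxon{i + 1:02d}" for i in range(n_taxa)]
    if gc3_targets is None:
        gc3_targets = list(np.linspace(30.0, 80.0, n_taxa))
    truth = FixtureTruth(seed=seed, gc3_targets=dict(zip(taxa, gc3_targets)))

    genes: list[tuple[str, Msa]] = []
    for g in range(n_genes):
        name = f"gene{g + 1}"
        # anchor taxa (first two) appear in every gene; others may drop out
        present = [
            t
            for i, t in enumerate(taxa)
            if i < 2 or rng.random() >= taxon_dropout
        ]
        site_positions = rng.choice(n_codons, size=min(n_serine_sites, n_codons), replace=False)
        serine_sites = sorted(int(s) + 1 for s in site_positions)
        rows = {t: [] for t in present}
        for site in range(n_codons):
            if site + 1 in serine_sites and serine_agn and serine_ucn:
                # one row gets AGN, another UCN, rest random serine class
                agn_taxon, ucn_taxon = rng.choice(len(present), size=2, replace=False)
                for r, t in enumerate(present):
                    if r == agn_taxon:
                        rows[t].append(serine_agn[rng.integers(len(serine_agn))])
                    elif r == ucn_taxon:
                        rows[t].append(serine_ucn[rng.integers(len(serine_ucn))])
                    else:
                        both = serine_agn + serine_ucn
                        rows[t].append(both[rng.integers(len(both))])
            else:
                # a conserved amino-acid column with per-taxon GC3 bias:
                # draw one codon, then synonymous variants per taxon
                base = pool[rng.integers(len(pool))]
                syn = [c for c in pool if code.codon_to_aa[c] == code.codon_to_aa[base]]
                for t in present:
                    rows[t].append(_pick_codon(rng, syn, truth.gc3_targets[t]))
        seqs = {t: "".join(rows[t]) for t in present}

        displaced = 0
        attempts = 0
        while displaced < n_displaced and attempts < 50 * n_displaced:
            attempts += 1
            t = present[rng.integers(len(present))]
            s = seqs[t]
            site = int(rng.integers(1, n_codons))  # codon site to gap out
            start = 3 * site
            if GAP in s:
                continue  # keep at most one displaced run per row
            # open a gap triple and strand the preceding residue at the
            # run's far end, emulating a misplaced gap-adjacent residue
            moved = s[start - 1]
            s2 = s[: start - 1] + GAP * 3 + moved + s[start + 3 :]
            seqs[t] = s2
            displaced += 1
        truth.serine_cooccurrence_sites[name] = serine_sites
        truth.displaced_residues[name] = displaced
        truth.taxa_per_gene[name] = list(present)
        genes.append((name, Msa(records=[(t, seqs[t]) for t in present])))
    return genes, truth
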