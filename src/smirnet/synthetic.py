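"""Desk-scale synthetic corpora with planted cluster structure.

Real inputs to the pipeline are a miRNA sequence corpus, a compound SMILES
corpus, and a list of experimentally supported SM-miRNA associations.
This module emulates all three at bench-test size: sequences are generated
as mutated copies of per-cluster ancestor strings (so latent-space
similarity has real structure to find), and associations are planted
preferentially between matched sequence clusters.  With the cluster boost
at 1 the association pattern is uniform noise and recovery must fail --
the negative control for the end-to-end test.

Chemical validity of the SMILES-like strings is plausible (templates are
real drug SMILES) but not enforced: the method consumes characters, not
molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import AssociationList, SequenceRecord

#: Short valid drug-like SMILES used as cluster ancestors (all length <= 50).
SMILES_TEMPLATES = (
    "CC(=O)OC1=CC=CC=C1C(=O)O",            # aspirin
    "CC(=O)NC1=CC=C(C=C1)O",               # paracetamol
    "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",       # ibuprofen
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",        # caffeine
    "CN1CCCC1C2=CC=CN=C2",                 # nicotine
    "C1=CC=C(C=C1)C(=O)O",                 # benzoic acid
    "C1=CC=C2C(=C1)C=CC=C2O",              # naphthol
    "CC1=CC(=O)C=CC1=O",                   # methylquinone
    "C1CCC(CC1)N",                         # cyclohexylamine
    "CC(C)NCC(O)C1=CC=C(O)C(O)=C1",        # isoprenaline
    "OCC1OC(O)C(O)C(O)C1O",                # glucose
    "CC12CCC3C(CCC4=CC(=O)CCC34)C1CCC2=O", # steroid core
    "C1=CN=CC=C1C(=O)N",                   # nicotinamide
    "CC(N)C(=O)O",                         # alanine
    "NC1=CC=C(C=C1)S(=O)(=O)N",            # sulfanilamide
    "COC1=CC=CC=C1OCC(O)CN",               # moprolol fragment
    "CN(C)CCC1=CNC2=CC=CC=C12",            # tryptamine
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",          # citric acid
    "CC1=CC=C(C=C1)S(=O)(=O)O",            # tosylate
    "C1CN(CCN1)C2=CC=CC=C2",               # phenylpiperazine
)

#: Characters eligible for point substitution in SMILES-like strings.
_SMILES_SUB_SET = ("C", "N", "O", "S")

_NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one synthetic study.

    Defaults give 60 entities per side in 6 matched clusters, a 10 percent
    per-position mutation rate within clusters, a baseline association
    density of 0.01, and a 20-fold boost for cluster-matched pairs --
    conditions under which similarity-driven link prediction should beat a
    random ranking by a clear margin.
    """

    n_mirna: int = 60
    n_sm: int = 60
    n_clusters: int = 6
    mirna_len_range: tuple[int, int] = (18, 24)
    smiles_len_max: int = 50
    mutation_rate: float = 0.1
    assoc_density: float = 0.01
    within_cluster_assoc_boost: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.n_clusters > min(self.n_mirna, self.n_sm):
            raise ValueError("more clusters than entities")
        if self.mirna_len_range[1] > 30:
            raise ValueError("miRNA lengths must stay within the 30-char maximum")
        if self.smiles_len_max > 50:
            raise ValueError("SMILES lengths must stay within the 50-char maximum")
        if self.within_cluster_assoc_boost < 1:
            raise ValueError("boost must be >= 1")


@dataclass(frozen=True)
class SyntheticBundle:
    """A generated study: corpora, associations, and the hidden truth."""

    mirna_records: tuple[SequenceRecord, ...]
    sm_records: tuple[SequenceRecord, ...]
    associations: AssociationList
    mirna_clusters: tuple[int, ...]
    sm_clusters: tuple[int, ...]
    cluster_match: tuple[int, ...]  # SM cluster k is matched to miRNA cluster cluster_match[k]


def _cluster_sizes(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def generate_mirna_corpus(
    spec: SyntheticSpec,
) -> tuple[list[SequenceRecord], list[int]]:
    """Clustered nucleotide strings: mutated copies of cluster ancestors."""
    rng = np.random.default_rng([spec.seed, 1])
    lo, hi = spec.mirna_len_range
    records: list[SequenceRecord] = []
    labels: list[int] = []
    idx = 0
    for k, size in enumerate(_cluster_sizes(spec.n_mirna, spec.n_clusters)):
        length = int(rng.integers(lo, hi + 1))
        ancestor = rng.choice(_NUCLEOTIDES, size=length)
        for _ in range(size):
            seq = ancestor.copy()
            hit = rng.random(length) < spec.mutation_rate
            for pos in np.nonzero(hit)[0]:
                alt = [c for c in _NUCLEOTIDES if c != seq[pos]]
                seq[pos] = alt[int(rng.integers(len(alt)))]
            records.append(
                SequenceRecord(f"mir{idx:04d}", "".join(seq), "mirna")
            )
            labels.append(k)
            idx += 1
    return records, labels


def generate_smiles_corpus(
    spec: SyntheticSpec,
) -> tuple[list[SequenceRecord], list[int]]:
    """Clustered SMILES-like strings derived from drug templates.

    Each cluster picks one template ancestor; members apply seeded point
    substitutions among {C, N, O, S} at the mutation rate.  All strings
    respect the 50-character maximum because the templates do.
    """
    rng = np.random.default_rng([spec.seed, 2])
    template_order = rng.permutation(len(SMILES_TEMPLATES))
    records: list[SequenceRecord] = []
    labels: list[int] = []
    idx = 0
    for k, size in enumerate(_cluster_sizes(spec.n_sm, spec.n_clusters)):
        ancestor = SMILES_TEMPLATES[template_order[k % len(SMILES_TEMPLATES)]]
        ancestor = ancestor[: spec.smiles_len_max]
        for _ in range(size):
            chars = list(ancestor)
            for pos, ch in enumerate(chars):
                if ch in _SMILES_SUB_SET and rng.random() < spec.mutation_rate:
                    alt = [c for c in _SMILES_SUB_SET if c != ch]
                    chars[pos] = alt[int(rng.integers(len(alt)))]
            records.append(
                SequenceRecord(f"sm{idx:04d}", "".join(chars), "smiles")
            )
            labels.append(k)
            idx += 1
    return records, labels


def generate_associations(
    mirna_records: list[SequenceRecord],
    sm_records: list[SequenceRecord],
    mirna_clusters: list[int],
    sm_clusters: list[int],
    spec: SyntheticSpec,
    max_retries: int = 10,
) -> tuple[AssociationList, list[int]]:
    """Plant associations preferentially between matched clusters.

    A seeded random bijection matches SM clusters to miRNA clusters; a
    pair is drawn with probability density * boost when cluster-matched
    (capped at 1) and density otherwise.  Regenerates with a shifted
    stream if no pair is drawn.
    """
    sm_ids = [r.id for r in sm_records]
    mirna_ids = [r.id for r in mirna_records]
    rng = np.random.default_rng([spec.seed, 3])
    match = list(rng.permutation(spec.n_clusters))
    p_in = min(1.0, spec.assoc_density * spec.within_cluster_assoc_boost)
    p_out = spec.assoc_density
    for attempt in range(max_retries):
        stream = np.random.default_rng([spec.seed, 3, attempt])
        pairs: set[tuple[str, str]] = set()
        for i, s in enumerate(sm_ids):
            matched_cluster = match[sm_clusters[i]]
            for j, m in enumerate(mirna_ids):
                p = p_in if mirna_clusters[j] == matched_cluster else p_out
                if stream.random() < p:
                    pairs.add((s, m))
        if pairs:
            return (
                AssociationList(pairs=pairs, sm_ids=sm_ids, mirna_ids=mirna_ids),
                match,
            )
    raise RuntimeError("no associations drawn after bounded retries")


def generate_bundle(spec: SyntheticSpec | None = None, **overrides) -> SyntheticBundle:
    """Generate corpora and associations as one reproducible bundle."""
    spec = spec or SyntheticSpec()
    if overrides:
        spec = replace(spec, **overrides)
    mirna_records, mirna_clusters = generate_mirna_corpus(spec)
    sm_records, sm_clusters = generate_smiles_corpus(spec)
    assoc, match = generate_associations(
        mirna_records, sm_records, mirna_clusters, sm_clusters, spec
    )
    return SyntheticBundle(
        mirna_records=tuple(mirna_records),
        sm_records=tuple(sm_records),
        associations=assoc,
        mirna_clusters=tuple(mirna_clusters),
        sm_clusters=tuple(sm_clusters),
        cluster_match=tuple(match),
    )
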