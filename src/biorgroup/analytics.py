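"""Validation analytics: stereocenter statistics, NP-likeness, timeouts.

Three independent checks on an expansion run or on any molecule collection:

* chiral-center statistics (defined vs defined+undefined tetrahedral
  stereocenters per molecule, and the fraction of molecules with at least
  one center) — the signature that separates natural-product-like from
  synthetic chemical space;
* a trainable natural-product-likeness scorer: per-fragment log10 ratio of
  smoothed relative frequencies of atom-centered circular fragments
  (radius 0–2) between a "natural" and a "synthetic" training collection,
  summed over a molecule's fragments and normalised by heavy-atom count;
* timeout sensitivity: coverage of the (query, candidate) matching attempts
  as a function of the per-pair budget, over a weight-stratified sample of
  queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from math import log10

from .compound_store import CandidateCompound, Store
from .molecules import GenericMolecule, count_heavy_atoms
from .rgroup_matcher import MatchConfig, expand_query


# ---------------------------------------------------------------------------
# Stereocenter statistics


@dataclass(frozen=True)
class StereoStats:
    """Collection-level chiral-center summary."""

    mean_defined: float
    mean_defined_plus_undefined: float
    frac_with_at_least_one: float


def stereocenter_counts(mol: Chem.Mol) -> Tuple[int, int]:
    """(defined, total) tetrahedral stereocenters; wildcards permitted.

    ``defined`` counts centers with assigned parity; ``total`` adds the
    potential-but-unassigned ones. Double-bond stereo is counted separately
    by :func:`double_bond_stereo_counts`.
    """
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    defined = sum(1 for _, code in centers if code != "?")
    return defined, len(centers)


def double_bond_stereo_counts(mol: Chem.Mol) -> Tuple[int, int]:
    """(defined, total) stereogenic double bonds."""
    stereo = Chem.FindPotentialStereo(mol)
    defined = total = 0
    for element in stereo:
        if element.type != Chem.StereoType.Bond_Double:
            continue
        total += 1
        if element.specified == Chem.StereoSpecified.Specified:
            defined += 1
    return defined, total


def collection_stereo_stats(collection: Sequence[Chem.Mol]) -> StereoStats:
    """Means and at-least-one fraction over a non-empty collection."""
    if not collection:
        raise ValueError("empty collection")
    counts = [stereocenter_counts(mol) for mol in collection]
    n = len(counts)
    return StereoStats(
        mean_defined=sum(d for d, _ in counts) / n,
        mean_defined_plus_undefined=sum(t for _, t in counts) / n,
        frac_with_at_least_one=sum(1 for _, t in counts if t > 0) / n,
    )


# ---------------------------------------------------------------------------
# NP-likeness scorer


@dataclass(frozen=True)
class FragmentScoreTable:
    """Fragment → contribution map trained on two labeled collections.

    Contributions are log10 ratios of smoothed relative fragment
    frequencies (natural over synthetic), so swapping the training
    collections negates every entry exactly.
    """

    scores: tuple  # ((fragment_key, contribution), ...)
    n_natural: int
    n_synthetic: int
    smoothing: float

    def as_dict(self) -> Dict[int, float]:
        return dict(self.scores)


def _fragment_counts(mol: Chem.Mol) -> Dict[int, int]:
    """Atom-centered circular fragment keys (radius 0-2) with multiplicity."""
    fp = rdMolDescriptors.GetMorganFingerprint(mol, 2)
    return dict(fp.GetNonzeroElements())


def train_np_scorer(
    natural: Sequence[Chem.Mol],
    synthetic: Sequence[Chem.Mol],
    smoothing: float = 1e-6,
) -> FragmentScoreTable:
    """Train the fragment-ratio scorer from two molecule collections.

    Each fragment's contribution is ``log10((f_nat + s) / (f_syn + s))``
    where the ``f`` are relative frequencies (fragment count over total
    fragment count in the collection) and ``s`` is the pseudo-count.
    """
    if not natural or not synthetic:
        raise ValueError("both training collections must be non-empty")

    def frequencies(mols):
        counts: Dict[int, int] = {}
        total = 0
        for mol in mols:
            for key, n in _fragment_counts(mol).items():
                counts[key] = counts.get(key, 0) + n
                total += n
        return {k: v / total for k, v in counts.items()}

    f_nat = frequencies(natural)
    f_syn = frequencies(synthetic)
    keys = sorted(set(f_nat) | set(f_syn))
    # difference of logs (not log of the quotient) so that swapping the
    # training collections negates every contribution exactly, bit for bit
    scores = tuple(
        (
            k,
            log10(f_nat.get(k, 0.0) + smoothing)
            - log10(f_syn.get(k, 0.0) + smoothing),
        )
        for k in keys
    )
    return FragmentScoreTable(
        scores=scores,
        n_natural=len(natural),
        n_synthetic=len(synthetic),
        smoothing=smoothing,
    )


def np_score(mol: Chem.Mol, table: FragmentScoreTable) -> float:
    """Sum of fragment contributions normalised by heavy-atom count.

    Fragments unseen in training contribute zero. Higher values indicate
    stronger resemblance to the natural training collection.
    """
    heavy = count_heavy_atoms(mol)
    if heavy == 0:
        raise ValueError("molecule has no heavy atoms")
    scores = table.as_dict()
    total = sum(
        n * scores.get(key, 0.0) for key, n in _fragment_counts(mol).items()
    )
    return total / heavy


# ---------------------------------------------------------------------------
# Timeout sensitivity


def stratified_sample(queries: Sequence[GenericMolecule], sample_size: int) -> list:
    """``sample_size`` queries evenly spaced along the sorted weight range.

    Uses indices ``round(i * (n-1) / (sample_size-1))`` on the sequence
    sorted by (weight, canonical SMILES); asking for more queries than
    exist returns them all with a warning.
    """
    ordered = sorted(queries, key=lambda q: (q.exact_mol_wt, q.smiles))
    n = len(ordered)
    if sample_size >= n:
        if sample_size > n:
            warnings.warn(
                f"sample_size {sample_size} exceeds number of queries {n}; using all",
                stacklevel=2,
            )
        return ordered
    if sample_size == 1:
        return [ordered[0]]
    idx = sorted({round(i * (n - 1) / (sample_size - 1)) for i in range(sample_size)})
    return [ordered[i] for i in idx]


def timeout_sensitivity(
    queries: Sequence[GenericMolecule],
    store: Store,
    timeouts: Sequence[float] = (2.0, 10.0, 20.0),
    sample_size: int = 50,
    config: MatchConfig = MatchConfig(),
    cost_model: Optional[Callable[[GenericMolecule, CandidateCompound], float]] = None,
) -> List[dict]:
    """Coverage of matching attempts per timeout, on a stratified sample.

    Coverage is evaluated (non-timed-out) pairs over total pairs; it is
    non-decreasing in the timeout. ``cost_model`` substitutes a simulated
    per-pair cost for wall-clock timing (see :func:`expand_query`).
    Returns one row per timeout with per-query timeout counts.
    """
    if not queries:
        raise ValueError("no queries supplied")
    if list(timeouts) != sorted(timeouts):
        raise ValueError("timeouts must be sorted ascending")
    sample = stratified_sample(queries, sample_size)
    rows = []
    for timeout in timeouts:
        run_config = MatchConfig(
            timeout_seconds=timeout,
            allow_hydrogen_substituent=config.allow_hydrogen_substituent,
            require_all_r_substituted=config.require_all_r_substituted,
            match_defined_stereo=config.match_defined_stereo,
        )
        total = 0
        timed_out = 0
        per_query: Dict[str, int] = {}
        for query in sample:
            candidates = sum(
                1 for _ in store.query_heavier_than(query.exact_mol_wt)
            )
            result = expand_query(query, store, run_config, cost_model=cost_model)
            n_timeouts = len(result.timed_out)
            total += candidates
            timed_out += n_timeouts
            per_query[query.smiles] = n_timeouts
        rows.append(
            {
                "timeout_seconds": timeout,
                "total_pairs": total,
                "evaluated_pairs": total - timed_out,
                "coverage": 1.0 if total == 0 else (total - timed_out) / total,
                "per_query_timeouts": per_query,
            }
        )
    return rows


def plot_score_distribution(scores, path, bins: int = 30) -> None:
    """Histogram of NP-likeness scores (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(list(scores), bins=bins, color="#4878d0", alpha=0.85)
    ax.set_xlabel("NP-likeness score")
    ax.set_ylabel("molecules")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
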