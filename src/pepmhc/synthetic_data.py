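"""Synthetic peptide corpora and binding-affinity benchmarks with known truth.

Two generators make every other module testable without external downloads:

* :func:`simulate_cleavage` emulates stochastic proteasome slicing of
  proteins: every inter-residue site is cut independently with a
  probability supplied per site or given by a residue-conditioned model
  (the proteasome cuts preferentially after hydrophobic and basic
  residues); fragments outside the 8-20 residue window are discarded.
  The resulting corpus is what the peptide language model pretrains on.

* :func:`make_benchmark` builds per-allele binding data from a hidden
  position-specific score matrix (an anchor-style motif over a 9-residue
  core): a peptide's energy is the best core-window score, mapped through
  a logistic curve to IC50 in (1, 50000] nM, calibrated per motif so that
  about 25% of random peptides fall below the 500 nM binder threshold.
  Train/test splits are decontaminated at 80% same-length sequence
  identity, and the noiseless energies are retained as ground truth for
  parameter-recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import similarity_overlap_audit
from .peptide_data import (
    AMINO_ACIDS, AffinityRecord, Inequality, MeasurementKind,
)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residues the internal cleavage model cuts after with elevated probability
#: (hydrophobic/aromatic and basic C-terminal preferences).
_PREFERRED_CTERM = set("AFILMVWYKR")

#: Default residue-conditioned cut probabilities; the mixture over a typical
#: composition gives a mean fragment length of roughly ten residues.
DEFAULT_RESIDUE_CUT_PROBS: dict[str, float] = {
    aa: (0.18 if aa in _PREFERRED_CTERM else 0.04) for aa in AMINO_ACIDS
}


@dataclass(frozen=True)
class CleavageModel:
    """Per-site cut probabilities for stochastic protein slicing.

    Either ``site_probs`` maps a protein identifier to its per-site cut
    probabilities (one per inter-residue position, length = len(protein)-1),
    e.g. parsed from an external cleavage predictor's output, or the
    residue-conditioned ``residue_probs`` (probability of a cut after each
    residue type) is used.  Fragments outside [min_len, max_len] are
    discarded.
    """

    residue_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_CUT_PROBS))
    site_probs: Mapping[str, Sequence[float]] | None = None
    min_len: int = 8
    max_len: int = 20

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        for aa, p in self.residue_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"cut probability for {aa!r} outside [0, 1]")

    def probs_for(self, protein_id: str, sequence: str) -> np.ndarray:
        if self.site_probs is not None and protein_id in self.site_probs:
            p = np.asarray(self.site_probs[protein_id], dtype=float)
            if len(p) != len(sequence) - 1:
                raise ValueError(
                    f"site-probability table for {protein_id!r} has length "
                    f"{len(p)}, expected {len(sequence) - 1}"
                )
            return p
        return np.array([self.residue_probs.get(ch, 0.0)
                         for ch in sequence[:-1]])


def _as_named_proteins(proteins) -> list[tuple[str, str]]:
    out = []
    for i, item in enumerate(proteins):
        if isinstance(item, str):
            out.append((str(i), item))
        elif isinstance(item, tuple):
            out.append((str(item[0]), str(item[1])))
        else:  # Bio.SeqRecord
            out.append((item.id, str(item.seq).upper()))
    return out


def simulate_cleavage(proteins, model: CleavageModel = CleavageModel(),
                      seed: int = 0, repeats: int = 1):
    """Stochastically slice proteins into peptides.

    Each inter-residue site is cut independently with its probability;
    ``repeats`` independent slicings are drawn per protein.  Returns
    ``(peptides, stats)`` where stats records fragment counts and the
    length histogram of the kept peptides.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    peptides: list[str] = []
    n_fragments = 0
    for pid, seq in _as_named_proteins(proteins):
        if len(seq) < 2:
            frags_all = [[seq]] * repeats if seq else []
        else:
            p = model.probs_for(pid, seq)
            frags_all = []
            for _ in range(repeats):
                cuts = np.flatnonzero(rng.random(len(p)) < p) + 1
                bounds = np.concatenate([[0], cuts, [len(seq)]])
                frags_all.append(
                    [seq[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
                )
        for frags in frags_all:
            n_fragments += len(frags)
            peptides.extend(
                f for f in frags if model.min_len <= len(f) <= model.max_len
            )
    hist: dict[int, int] = {}
    for pep in peptides:
        hist[len(pep)] = hist.get(len(pep), 0) + 1
    stats = {
        "n_proteins": len(proteins),
        "n_fragments": n_fragments,
        "n_kept": len(peptides),
        "length_histogram": dict(sorted(hist.items())),
    }
    return peptides, stats


# ---------------------------------------------------------------------------
# Motif-based affinity generator
# ---------------------------------------------------------------------------

#: y-space value of the 500 nM class I binder threshold under the 50000 cap.
_S_BINDER = 1.0 - math.log(500.0) / math.log(50000.0)


@dataclass(frozen=True)
class AlleleMotif:
    """Hidden position-specific score matrix defining one allele's truth.

    ``matrix`` is (core_length, 20); a peptide's energy is the maximum
    sliding-window sum.  ``scale``/``offset`` parameterize the logistic
    energy -> IC50 map, standardized per motif so about a quarter of random
    peptides are binders (< 500 nM).
    """

    allele_id: str
    matrix: np.ndarray
    core_length: int = 9
    noise_sd: float = 0.1
    scale: float = 1.0
    offset: float = 0.0
    cap_nm: float = 50000.0


def make_allele_motif(seed: int, sharpness: float = 1.0,
                      allele_id: str | None = None, core_length: int = 9,
                      noise_sd: float = 0.1,
                      binder_fraction: float = 0.25) -> AlleleMotif:
    """Draw an anchor-style motif: 2-3 high-contrast positions, rest near-flat.

    ``sharpness`` scales all scores; as it approaches 0 every peptide has
    near-equal energy.  The logistic IC50 calibration places the
    ``binder_fraction`` quantile of the random-peptide energy distribution
    at the 500 nM binder threshold.
    """
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    rng = np.random.default_rng(seed)
    n_anchors = int(rng.integers(2, 4))
    anchors = rng.choice(core_length, size=n_anchors, replace=False)
    matrix = 0.1 * sharpness * rng.normal(size=(core_length, 20))
    matrix[anchors] = sharpness * rng.normal(size=(n_anchors, 20))

    # random-peptide energy moments for a core-length peptide (uniform residues)
    mu = float(matrix.mean(axis=1).sum())
    sigma = float(np.sqrt(matrix.var(axis=1).sum()))
    from scipy.stats import norm

    q = float(norm.ppf(1.0 - binder_fraction))
    logit_s = math.log(_S_BINDER / (1.0 - _S_BINDER))
    scale = 2.0 / max(sigma, 1e-12)
    offset = mu + q * sigma - logit_s / scale
    return AlleleMotif(
        allele_id=allele_id or f"SYN-{seed:04d}",
        matrix=matrix, core_length=core_length, noise_sd=noise_sd,
        scale=scale, offset=offset,
    )


def motif_energy(motif: AlleleMotif, peptide: str) -> float:
    """Noiseless energy: the best-scoring alignment of peptide and core.

    Peptides at least as long as the core score their best core-length
    window (max over sliding windows); shorter peptides slide *within* the
    core and score their best offset, so e.g. 8-mers remain scoreable under
    a 9-residue motif.
    """
    if not peptide:
        raise ValueError("empty peptide")
    L, k = len(peptide), motif.core_length
    idx = np.array([_AA_INDEX[ch] for ch in peptide])
    best = -np.inf
    if L >= k:
        for start in range(L - k + 1):
            s = float(motif.matrix[np.arange(k), idx[start : start + k]].sum())
            best = max(best, s)
    else:
        for offset in range(k - L + 1):
            s = float(motif.matrix[offset + np.arange(L), idx].sum())
            best = max(best, s)
    return best


def energy_to_ic50(motif: AlleleMotif, energy) -> np.ndarray | float:
    """Logistic map: ic50 = cap^(1 - sigmoid(scale*(energy - offset)))."""
    from scipy.special import expit

    s = expit(motif.scale * (np.asarray(energy, dtype=float) - motif.offset))
    ic50 = motif.cap_nm ** (1.0 - s)
    return float(ic50) if np.isscalar(energy) else ic50


def simulate_affinity(motif: AlleleMotif, peptide: str,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      qual_prob: float = 0.0,
                      qual_bound_nm: float = 50000.0) -> AffinityRecord:
    """Draw one measurement: noisy motif energy mapped to IC50.

    With probability ``qual_prob`` the record is emitted as qualitative
    (inequality ``>`` at ``qual_bound_nm``) instead of quantitative,
    mimicking assays that report non-binders only as a censoring bound.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    energy = motif_energy(motif, peptide) + rng.normal(0.0, motif.noise_sd)
    if qual_prob > 0 and rng.random() < qual_prob:
        return AffinityRecord(
            allele_id=motif.allele_id, peptide=peptide,
            ic50_nm=qual_bound_nm, inequality=Inequality.GT,
            kind=MeasurementKind.qualitative,
        )
    return AffinityRecord(
        allele_id=motif.allele_id, peptide=peptide,
        ic50_nm=float(energy_to_ic50(motif, energy)),
        inequality=Inequality.EQ, kind=MeasurementKind.quantitative,
    )


def random_peptides(rng: np.random.Generator, n: int,
                    length_range: tuple[int, int]) -> list[str]:
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    aa = np.array(list(AMINO_ACIDS))
    return ["".join(aa[rng.integers(0, 20, size=L)]) for L in lengths]


@dataclass
class Benchmark:
    """A synthetic benchmark: records plus the noiseless ground truth."""

    train: list[AffinityRecord]
    test: list[AffinityRecord]
    truth: pd.DataFrame  # columns: allele, peptide, energy, split
    manifest: dict


def make_benchmark(n_alleles: int = 1, n_train: int = 2000, n_test: int = 500,
                   qual_fraction: float = 0.0,
                   length_range: tuple[int, int] = (8, 11), seed: int = 0,
                   sharpness: float = 1.0, noise_sd: float = 0.05,
                   core_length: int = 9,
                   identity_threshold: float = 0.8) -> Benchmark:
    """Generate per-allele train/test affinity data with known energies.

    The test set is decontaminated against the training set: candidates with
    a same-length training peptide at >= ``identity_threshold`` positional
    identity (or appearing in training verbatim) are rejected and redrawn.
    """
    if min(n_alleles, n_train, n_test) < 1:
        raise ValueError("sizes must be positive")
    ss = np.random.SeedSequence(seed)
    train, test, rows = [], [], []
    for a, child in enumerate(ss.spawn(n_alleles)):
        state = child.generate_state(2)
        motif = make_allele_motif(
            int(state[0]) % 2**31, sharpness=sharpness,
            allele_id=f"SYN-A-{a:04d}", core_length=core_length,
            noise_sd=noise_sd,
        )
        rng = np.random.default_rng(int(state[1]) % 2**31)

        train_pep = list(dict.fromkeys(random_peptides(rng, n_train, length_range)))
        while len(train_pep) < n_train:
            extra = random_peptides(rng, n_train - len(train_pep), length_range)
            train_pep = list(dict.fromkeys(train_pep + extra))

        # recalibrate the logistic IC50 map on this benchmark's own length
        # mix (max-over-windows inflates longer peptides' energies, so the
        # core-length analytic calibration would overshoot the binder share)
        energies = np.array([motif_energy(motif, p) for p in train_pep])
        from dataclasses import replace as _replace

        scale = 2.0 / max(float(energies.std()), 1e-12)
        logit_s = math.log(_S_BINDER / (1.0 - _S_BINDER))
        offset = float(np.quantile(energies, 0.75)) - logit_s / scale
        motif = _replace(motif, scale=scale, offset=offset)

        test_pep: list[str] = []
        while len(test_pep) < n_test:
            cand = random_peptides(rng, 2 * (n_test - len(test_pep)), length_range)
            cand = list(dict.fromkeys(cand))
            flagged = set(
                similarity_overlap_audit(train_pep, cand, identity_threshold)
                ["peptide"]
            )
            pool = set(test_pep)
            for p in cand:
                if p not in flagged and p not in pool:
                    test_pep.append(p)
                    pool.add(p)
                    if len(test_pep) == n_test:
                        break

        for split, peps, recs in (("train", train_pep, train),
                                  ("test", test_pep, test)):
            for p in peps:
                recs.append(simulate_affinity(
                    motif, p, rng=rng, qual_prob=qual_fraction))
                rows.append((motif.allele_id, p, motif_energy(motif, p), split))

    truth = pd.DataFrame(rows, columns=["allele", "peptide", "energy", "split"])
    manifest = {
        "seed": seed, "n_alleles": n_alleles, "n_train": n_train,
        "n_test": n_test, "qual_fraction": qual_fraction,
        "length_range": list(length_range), "sharpness": sharpness,
        "noise_sd": noise_sd, "core_length": core_length,
        "identity_threshold": identity_threshold,
    }
    return Benchmark(train=train, test=test, truth=truth, manifest=manifest)


# ---------------------------------------------------------------------------
# Protein generator (cleavage-simulation input)
# ---------------------------------------------------------------------------

#: Approximate residue frequencies of the human proteome (UniProt statistics,
#: rounded); proteins drawn from these are compositionally realistic even
#: though they carry no higher-order structure.
HUMAN_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.012, "Y": 0.027, "V": 0.060,
}


def random_proteins(seed: int, n: int, length: int = 400,
                    frequencies: Mapping[str, float] | None = None) -> list[str]:
    """Sample protein sequences with proteome-like residue composition."""
    rng = np.random.default_rng(seed)
    freqs = frequencies or HUMAN_AA_FREQUENCIES
    p = np.array([freqs[a] for a in AMINO_ACIDS], dtype=float)
    p = p / p.sum()
    aa = np.array(list(AMINO_ACIDS))
    return ["".join(rng.choice(aa, size=length, p=p)) for _ in range(n)]


# ---------------------------------------------------------------------------
# Markov-chain corpora (known-entropy fixtures for language-model checks)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkovChain:
    """A first-order residue chain with known prediction ceiling."""

    start: np.ndarray       # (20,) distribution of the first residue
    transition: np.ndarray  # (20, 20) row-stochastic

    def bayes_accuracy(self, peptides: Sequence[str]) -> float:
        """Best possible next-token accuracy of any predictor on this corpus.

        The optimal predictor emits the argmax of the start distribution for
        the first residue and the argmax transition row afterwards; its
        expected accuracy is the corresponding max-probability, averaged
        over the actual contexts in ``peptides``.
        """
        p_first = float(self.start.max())
        row_max = self.transition.max(axis=1)
        total = 0.0
        n = 0
        for pep in peptides:
            total += p_first
            n += len(pep)
            for ch in pep[:-1]:
                total += float(row_max[_AA_INDEX[ch]])
        return total / n


def make_markov_chain(seed: int, concentration: float = 0.2) -> MarkovChain:
    """Draw a random chain with Dirichlet(concentration) rows.

    Small concentration gives peaked rows (high Bayes accuracy); large gives
    near-uniform rows (Bayes accuracy near the 1/20 chance level).
    """
    rng = np.random.default_rng(seed)
    T = rng.dirichlet(np.full(20, concentration), size=20)
    # start from the stationary distribution of T
    w, v = np.linalg.eig(T.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1))])
    pi = np.abs(pi) / np.abs(pi).sum()
    return MarkovChain(start=pi, transition=T)


def markov_corpus(chain: MarkovChain, n_peptides: int,
                  length_range: tuple[int, int], seed: int) -> list[str]:
    """Sample peptides from a first-order Markov chain over residues."""
    rng = np.random.default_rng(seed)
    aa = list(AMINO_ACIDS)
    lo, hi = length_range
    out = []
    for _ in range(n_peptides):
        L = int(rng.integers(lo, hi + 1))
        idx = [int(rng.choice(20, p=chain.start))]
        for _ in range(L - 1):
            idx.append(int(rng.choice(20, p=chain.transition[idx[-1]])))
        out.append("".join(aa[i] for i in idx))
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_peptides_txt(peptides: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(peptides) + "\n")


def write_peptides_fasta(peptides: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peptides):
            fh.write(f">peptide_{i}\n{p}\n")


def write_benchmark(bench: Benchmark, outdir: str | Path) -> None:
    """Write train/test CSVs, the truth table, and a manifest of parameters."""
    from .peptide_data import write_affinity_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_affinity_table(bench.train, outdir / "train.csv")
    write_affinity_table(bench.test, outdir / "test.csv")
    bench.truth.to_csv(outdir / "truth.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(bench.manifest, indent=2))
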