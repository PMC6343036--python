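"""Moment estimators for recombination parameters, and NG86 pairwise dN/dS.

r/m and rho/theta quantify how much recombination, relative to point mutation,
alters sites (r/m) and how often it strikes (rho/theta). Here both are moment
estimates computed directly from consensus events and the polymorphic-site
counts of the core alignment; they deliberately involve no genealogy inference
and are labeled "moment estimate" in every output:

    rho/theta = n_events / m_hat           (events per clonal mutation)
    nu_hat    = SNP density inside events
    delta_hat = mean event length (bp)
    r/m       = rho/theta * delta_hat * nu_hat   (identity, by construction)

where m_hat counts polymorphic complete-case columns outside all events.

dN/dS uses Nei-Gojobori (1986) pathway counting with Jukes-Cantor correction:
fractional synonymous sites from the 9 single-nucleotide neighbors of each
codon (mutations to stop codons excluded from denominators), observed
differences averaged over all minimal mutational pathways, and
dX = -3/4 ln(1 - 4/3 pX).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import log

import numpy as np

from Bio.Data.CodonTable import standard_dna_table

from .detect import _codes, polymorphic_sites
from .errors import MissingDataError

_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


@dataclass
class RecombParams:
    """Moment estimates of recombination intensity for one species."""

    rho_theta: float
    r_m: float
    delta_hat: float
    nu_hat: float
    n_events: int
    m_hat: int
    saturated: bool = False
    estimator: str = "moment estimate"


def estimate_recomb_params(block, events) -> RecombParams:
    """Moment estimates from a core alignment block and its consensus events.

    Polymorphic-site counting is complete-case (columns without gaps or N in
    any strain). With no polymorphism left outside events the ratios are
    reported as infinite and flagged saturated.
    """
    poly = polymorphic_sites(block)
    _, valid = _codes(block)
    cc = valid.all(axis=0)
    poly = poly[cc[poly]]
    inside = np.zeros(block.length, dtype=bool)
    for ev in events:
        inside[ev.start_col : ev.end_col] = True
    n_events = len(events)
    m_hat = int((~inside[poly]).sum())
    poly_in = int(inside[poly].sum())
    cols_in = int((inside & cc).sum())
    nu_hat = poly_in / cols_in if cols_in else 0.0
    delta_hat = float(np.mean([ev.size for ev in events])) if events else 0.0
    if m_hat == 0:
        rho_theta = float("inf") if n_events else 0.0
        r_m = float("inf") if n_events else 0.0
        return RecombParams(rho_theta, r_m, delta_hat, nu_hat, n_events, m_hat, saturated=True)
    rho_theta = n_events / m_hat
    r_m = rho_theta * delta_hat * nu_hat
    return RecombParams(rho_theta, r_m, delta_hat, nu_hat, n_events, m_hat)


# ---------------------------------------------------------------------------
# NG86


@lru_cache(maxsize=None)
def codon_site_counts(codon: str):
    """(N, S): potential nonsynonymous/synonymous sites of one codon.

    At each position the synonymous fraction is the number of synonymous
    single-nucleotide changes over the number of non-stop changes; N + S = 3.
    """
    if codon in _STOPS:
        raise ValueError("stop codon has no site counts")
    aa = _TABLE[codon]
    S = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            valid += 1
            if _TABLE[alt] == aa:
                syn += 1
        if valid:
            S += syn / valid
    return 3.0 - S, S


@lru_cache(maxsize=None)
def codon_diff_counts(c1: str, c2: str):
    """(Nd, Sd) between two codons, averaged over all minimal mutational
    pathways; pathways passing through a stop codon are excluded (all pathways
    are used if every one passes through a stop)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((through_stop, steps))
    usable = [steps for stop, steps in paths if not stop] or [steps for _, steps in paths]
    nd = sd = 0.0
    for steps in usable:
        for a, b in steps:
            if a in _STOPS or b in _STOPS:
                nd += 1.0  # counted as nonsynonymous on stop-crossing fallback paths
            elif _TABLE[a] == _TABLE[b]:
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return nd / k, sd / k


@dataclass
class CodonPairCounts:
    N: float
    S: float
    Nd: float
    Sd: float
    n_codons: int

    @property
    def pN(self):
        return self.Nd / self.N if self.N else 0.0

    @property
    def pS(self):
        return self.Sd / self.S if self.S else 0.0

    @staticmethod
    def _jc(p):
        if p >= 0.75:
            return float("nan")
        return -0.75 * log(1 - 4 * p / 3)

    @property
    def dN(self):
        return self._jc(self.pN)

    @property
    def dS(self):
        return self._jc(self.pS)

    @property
    def dnds(self):
        """dN/dS, or None when undefined (dS == 0 or a saturated distance)."""
        dn, ds = self.dN, self.dS
        if ds == 0 or np.isnan(ds) or np.isnan(dn):
            return None
        return dn / ds


def ng86_pairwise(seq1: str, seq2: str) -> CodonPairCounts:
    """NG86 counts for one codon-aligned sequence pair.

    Codons containing gaps, ambiguity codes or stops in either sequence are
    excluded from the comparison; sequence length must be a multiple of 3.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("sequences must be codon-aligned (equal length, multiple of 3)")
    N = S = Nd = Sd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if any(b not in _BASES for b in c1 + c2) or c1 in _STOPS or c2 in _STOPS:
            continue
        n1, s1 = codon_site_counts(c1)
        n2, s2 = codon_site_counts(c2)
        N += (n1 + n2) / 2
        S += (s1 + s2) / 2
        nd, sd = codon_diff_counts(c1, c2)
        Nd += nd
        Sd += sd
        n_codons += 1
    return CodonPairCounts(N, S, Nd, Sd, n_codons)


def species_dnds(pair_counts) -> tuple:
    """Mean of the defined per-gene dN/dS ratios and the undefined count."""
    counts = list(pair_counts)
    if not counts:
        raise MissingDataError("no ortholog pairs supplied")
    ratios = []
    undefined = 0
    for c in counts:
        r = c.dnds if isinstance(c, CodonPairCounts) else c
        if r is None or (isinstance(r, float) and np.isnan(r)):
            undefined += 1
        else:
            ratios.append(float(r))
    mean = float(np.mean(ratios)) if ratios else None
    return mean, undefined
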