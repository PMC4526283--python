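"""Profile hidden Markov models over amino acids.

The model is the usual match/insert/delete ladder with ``L`` match columns.
Transitions are stored per column ``j`` as the seven probabilities out of the
column-``j`` states: ``M_j->M_{j+1}``, ``M_j->I_j``, ``M_j->D_{j+1}``,
``I_j->M_{j+1}``, ``I_j->I_j``, ``D_j->M_{j+1}``, ``D_j->D_{j+1}``.  Row 0 is
the begin state (treated as ``M_0``); the end state is ``M_{L+1}``, so the
row-``L`` match/insert/delete exits lead to the end.

Three things distinguish these models from a stock ``hmmbuild`` profile and
are the reason this module exists:

* **Close-homolog priors.**  Assembly targets close homologs, so sequence
  weighting is disabled and the transition prior means for ``D->M`` and
  ``I->M`` are 0.95 (``D->D``/``I->I`` 0.05), strongly discouraging long
  nonproductive insert/delete excursions during graph search.
* **A reversed twin.**  :func:`build_reverse_model` trains on the
  column-reversed alignment so paths can be extended leftwards from a seed
  that lands mid-model.
* **Null-normalised, monotonicity-corrected weights.**  Match emissions are
  scored as log-odds against a fixed background; because the best log-odds
  per column can be positive, the per-column maximum ``c_j`` is subtracted
  from every edge entering column ``j``'s match or delete state ("modified"
  weights), making all edge weights non-positive so A*'s heuristic stays
  admissible.  Raw (unmodified) weights are kept for reporting bit scores.

Insert emissions are pinned to the background, so normalised insert
emissions contribute exactly zero and non-match edges carry transition-only
weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import GAP_CHARS, FormatError, MultipleAlignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
TRANSITIONS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
LN2 = math.log(2.0)

# Swiss-Prot-style amino-acid frequencies (order ACDEFGHIKLMNPQRSTVWY),
# normalised at import; a uniform 1/20 table is available by flag.
_SWISSPROT = np.array(
    [
        0.0826, 0.0136, 0.0546, 0.0672, 0.0386, 0.0708, 0.0227, 0.0598,
        0.0580, 0.0966, 0.0241, 0.0406, 0.0475, 0.0393, 0.0553, 0.0660,
        0.0534, 0.0687, 0.0109, 0.0292,
    ]
)
BACKGROUND = _SWISSPROT / _SWISSPROT.sum()
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


class ModelError(ValueError):
    """The alignment or model file cannot yield a usable profile."""


class IllegalTransition(ValueError):
    """A state pair that the profile grammar does not connect."""


@dataclass
class PriorConfig:
    """Pseudocount configuration for model training.

    ``emission_pseudocount`` is a uniform Laplace count per residue.
    Transition rows receive ``transition_prior_weight`` pseudo-observations
    distributed by the prior means: uniform for match rows, and the
    close-homolog 0.95/0.05 split for delete and insert rows.
    """

    emission_pseudocount: float = 1.0 / 20.0
    transition_prior_weight: float = 1.0
    delete_to_match: float = 0.95
    insert_to_match: float = 0.95
    uniform_background: bool = False


@dataclass
class ProfileHMM:
    name: str
    L: int
    match_emission: np.ndarray  # (L+1, 20); row 0 unused
    insert_emission: np.ndarray  # (L+1, 20)
    trans: dict[str, np.ndarray]  # each (L+1,)
    background: np.ndarray  # (20,)
    direction: str = "forward"
    _log_trans: Optional[dict[str, np.ndarray]] = field(default=None, repr=False)
    _logodds: Optional[np.ndarray] = field(default=None, repr=False)
    _max_emission_log: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def log_trans(self) -> dict[str, np.ndarray]:
        if self._log_trans is None:
            with np.errstate(divide="ignore"):
                self._log_trans = {t: np.log(self.trans[t]) for t in TRANSITIONS}
        return self._log_trans

    @property
    def logodds_match(self) -> np.ndarray:
        """log(match_emission / background), -inf where emission is zero."""
        if self._logodds is None:
            with np.errstate(divide="ignore"):
                self._logodds = np.log(self.match_emission) - np.log(self.background)
            self._logodds[0, :] = 0.0
        return self._logodds

    @property
    def max_emission_log(self) -> np.ndarray:
        """``c_j = log max_a(match_emission[j][a] / background[a])``; c_0 = 0."""
        if self._max_emission_log is None:
            c = self.logodds_match.max(axis=1)
            c[0] = 0.0
            self._max_emission_log = c
        return self._max_emission_log

    def emission_logodds(self, j: int, aa: str) -> float:
        """Null-normalised match emission log-odds in nats; insert states
        score 0 by convention; unknown residues (stops, X) score -inf."""
        idx = AA_INDEX.get(aa)
        if idx is None:
            return -math.inf
        return float(self.logodds_match[j, idx])

    def consensus(self) -> str:
        """Argmax amino acid per match column."""
        return "".join(
            AMINO_ACIDS[int(np.argmax(self.match_emission[j]))] for j in range(1, self.L + 1)
        )


def match_columns(aln: MultipleAlignment, symfrac: float = 0.5) -> list[int]:
    """Alignment columns whose gap fraction is below ``symfrac`` (0-based)."""
    n = len(aln.records)
    cols = []
    for c in range(aln.n_columns):
        gaps = sum(1 for r in aln.records if r.residues[c] in GAP_CHARS)
        if gaps / n < symfrac:
            cols.append(c)
    return cols


def _state_path(residues: str, col_to_j: dict[int, int]) -> list[tuple[str, int]]:
    """Plan7-style state path for one aligned sequence; begin is ("M", 0).

    Residues in non-match columns become inserts at the model column of the
    last match column passed.  The terminal end marker is ("E", -1).
    """
    path: list[tuple[str, int]] = [("M", 0)]
    cur_j = 0
    for c, ch in enumerate(residues):
        j = col_to_j.get(c)
        if j is not None:
            path.append(("D", j) if ch in GAP_CHARS else ("M", j))
            cur_j = j
        elif ch not in GAP_CHARS:
            path.append(("I", cur_j))
    path.append(("E", -1))
    return path


def _transition_type(a: tuple[str, int], b: tuple[str, int]) -> Optional[tuple[str, int]]:
    """(transition name, row) for consecutive path states; None for the
    plan7-illegal D<->I adjacencies, which are simply not counted."""
    sa, ja = a
    sb, jb = b
    if sb == "E":
        return {"M": "MM", "I": "IM", "D": "DM"}[sa], ja
    if sa == "M":
        if sb == "M":
            return "MM", ja
        if sb == "I":
            return "MI", ja
        return "MD", ja
    if sa == "I":
        if sb == "M":
            return "IM", ja
        if sb == "I":
            return "II", ja
        return None
    if sb == "D":
        return "DD", ja
    if sb == "M":
        return "DM", ja
    return None


def build_from_alignment(
    aln: MultipleAlignment,
    priors: Optional[PriorConfig] = None,
    symfrac: float = 0.5,
    name: str = "model",
    direction: str = "forward",
) -> ProfileHMM:
    """Train a profile from a protein alignment with no sequence weighting.

    Every sequence counts with weight one (the close-homolog setting).
    Emissions get a uniform Laplace pseudocount; transition rows mix observed
    counts with the prior means described in :class:`PriorConfig`, so with
    zero observed delete events ``t(D->M) = 0.95`` exactly.
    """
    priors = priors or PriorConfig()
    mcols = match_columns(aln, symfrac)
    L = len(mcols)
    if L == 0:
        raise ModelError(f"alignment {name!r} yields zero match columns")
    col_to_j = {c: j + 1 for j, c in enumerate(mcols)}

    tcounts = {t: np.zeros(L + 1) for t in TRANSITIONS}
    ecounts = np.zeros((L + 1, 20))
    for rec in aln.records:
        path = _state_path(rec.residues.upper(), col_to_j)
        for c, ch in enumerate(rec.residues.upper()):
            j = col_to_j.get(c)
            if j is not None and ch not in GAP_CHARS:
                idx = AA_INDEX.get(ch)
                if idx is not None:
                    ecounts[j, idx] += 1
        for a, b in zip(path, path[1:]):
            tr = _transition_type(a, b)
            if tr is not None:
                tname, row = tr
                tcounts[tname][row] += 1

    alpha = priors.emission_pseudocount
    me = (ecounts + alpha) / (ecounts.sum(axis=1, keepdims=True) + 20 * alpha)

    w = priors.transition_prior_weight
    trans = {t: np.zeros(L + 1) for t in TRANSITIONS}
    for j in range(L + 1):
        cmm, cmi, cmd = tcounts["MM"][j], tcounts["MI"][j], tcounts["MD"][j]
        denom = cmm + cmi + cmd + w
        trans["MM"][j] = (cmm + w / 3.0) / denom
        trans["MI"][j] = (cmi + w / 3.0) / denom
        trans["MD"][j] = (cmd + w / 3.0) / denom
        cim, cii = tcounts["IM"][j], tcounts["II"][j]
        denom = cim + cii + w
        trans["IM"][j] = (cim + w * priors.insert_to_match) / denom
        trans["II"][j] = (cii + w * (1.0 - priors.insert_to_match)) / denom
        cdm, cdd = tcounts["DM"][j], tcounts["DD"][j]
        denom = cdm + cdd + w
        trans["DM"][j] = (cdm + w * priors.delete_to_match) / denom
        trans["DD"][j] = (cdd + w * (1.0 - priors.delete_to_match)) / denom
    # Row L's MD/DD would lead past the end; fold them into the M/D exits.
    trans["MM"][L] += trans["MD"][L]
    trans["MD"][L] = 0.0
    trans["DM"][L] += trans["DD"][L]
    trans["DD"][L] = 0.0
    # There is no D_0 state; pin its row to the format convention.
    trans["DM"][0] = 1.0
    trans["DD"][0] = 0.0

    background = UNIFORM_BACKGROUND if priors.uniform_background else BACKGROUND
    me[0, :] = background
    insert_em = np.tile(background, (L + 1, 1))
    return ProfileHMM(
        name=name,
        L=L,
        match_emission=me,
        insert_emission=insert_em,
        trans=trans,
        background=background.copy(),
        direction=direction,
    )


def build_reverse_model(
    aln: MultipleAlignment,
    priors: Optional[PriorConfig] = None,
    symfrac: float = 0.5,
    name: str = "model",
) -> ProfileHMM:
    """Train on the column-reversed alignment (residue order reversed)."""
    reversed_aln = MultipleAlignment(
        [
            type(rec)(id=rec.id, description=rec.description, residues=rec.residues[::-1])
            for rec in aln.records
        ],
        aln.n_columns,
    )
    return build_from_alignment(
        reversed_aln, priors=priors, symfrac=symfrac, name=name, direction="reversed"
    )


# ---------------------------------------------------------------------------
# HMMER3 ASCII model format (the subset of fields this tool uses)

def _prob_to_field(p: float) -> str:
    if p <= 0.0:
        return "*"
    return f"{-math.log(p):.5f}"


def _field_to_prob(tok: str) -> float:
    if tok == "*":
        return 0.0
    return math.exp(-float(tok))


def write_hmmer3(model: ProfileHMM, path) -> None:
    """Write the model as a HMMER3/f ASCII file (probability subset)."""
    with open(path, "wt") as fh:
        fh.write("HMMER3/f [hmmasm profile subset]\n")
        fh.write(f"NAME  {model.name}\n")
        fh.write(f"LENG  {model.L}\n")
        fh.write("ALPH  amino\n")
        fh.write("HMM          " + "        ".join(AMINO_ACIDS) + "\n")
        fh.write(
            "            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n"
        )
        bg = "  ".join(_prob_to_field(p) for p in model.background)
        fh.write(f"  COMPO   {bg}\n")
        ins0 = "  ".join(_prob_to_field(p) for p in model.insert_emission[0])
        fh.write(f"          {ins0}\n")
        t = model.trans
        row0 = [t["MM"][0], t["MI"][0], t["MD"][0], t["IM"][0], t["II"][0]]
        fh.write(
            "          "
            + "  ".join(_prob_to_field(p) for p in row0)
            + "  0.00000  *\n"
        )
        for j in range(1, model.L + 1):
            mvals = "  ".join(_prob_to_field(p) for p in model.match_emission[j])
            fh.write(f"{j:7d}   {mvals}\n")
            ivals = "  ".join(_prob_to_field(p) for p in model.insert_emission[j])
            fh.write(f"          {ivals}\n")
            trow = [t[name][j] for name in TRANSITIONS]
            fh.write("          " + "  ".join(_prob_to_field(p) for p in trow) + "\n")
        fh.write("//\n")


def parse_hmmer3(path) -> ProfileHMM:
    """Parse a HMMER3 ASCII amino-acid model (HMMER3/b or /f dialects).

    Stored negative-log values are converted back to probabilities; ``*``
    means probability zero.  The COMPO line, when present, supplies the
    background; otherwise the built-in table is used.  Extra per-node
    annotation columns (MAP/CONS/RF/MM/CS) are ignored.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("HMMER3"):
        raise FormatError(f"{path}: not a HMMER3 ASCII model file")
    name = "model"
    leng = None
    alph = None
    i = 1
    while i < len(lines) and not lines[i].startswith("HMM "):
        parts = lines[i].split(None, 1)
        if len(parts) == 2:
            key, val = parts
            if key == "NAME":
                name = val.strip()
            elif key == "LENG":
                leng = int(val)
            elif key == "ALPH":
                alph = val.strip().lower()
        i += 1
    if i >= len(lines):
        raise FormatError(f"{path}: missing HMM section")
    if alph != "amino":
        raise ModelError(f"{path}: unsupported alphabet {alph!r} (amino only)")
    if leng is None or leng < 1:
        raise FormatError(f"{path}: missing or invalid LENG")
    i += 2  # skip the residue header and transition-name header lines

    background = BACKGROUND.copy()
    toks = lines[i].split()
    if toks and toks[0] == "COMPO":
        background = np.array([_field_to_prob(t) for t in toks[1:21]])
        i += 1
    L = leng
    insert_em = np.zeros((L + 1, 20))
    me = np.zeros((L + 1, 20))
    trans = {t: np.zeros(L + 1) for t in TRANSITIONS}

    toks = lines[i].split()
    if len(toks) < 20:
        raise FormatError(f"{path}: malformed node-0 insert emission line")
    insert_em[0] = [_field_to_prob(t) for t in toks[:20]]
    i += 1
    toks = lines[i].split()
    if len(toks) < 7:
        raise FormatError(f"{path}: malformed node-0 transition line")
    for t, tok in zip(TRANSITIONS, toks[:7]):
        trans[t][0] = _field_to_prob(tok)
    i += 1

    for j in range(1, L + 1):
        toks = lines[i].split()
        if not toks or toks[0] != str(j):
            raise FormatError(f"{path}: expected node {j}, got {lines[i][:30]!r}")
        me[j] = [_field_to_prob(t) for t in toks[1:21]]
        i += 1
        toks = lines[i].split()
        insert_em[j] = [_field_to_prob(t) for t in toks[:20]]
        i += 1
        toks = lines[i].split()
        for t, tok in zip(TRANSITIONS, toks[:7]):
            trans[t][j] = _field_to_prob(tok)
        i += 1
    if i >= len(lines) or not lines[i].startswith("//"):
        raise FormatError(f"{path}: missing // terminator")
    me[0, :] = background
    return ProfileHMM(
        name=name,
        L=L,
        match_emission=me,
        insert_emission=insert_em,
        trans=trans,
        background=background,
        direction="forward",
    )


# ---------------------------------------------------------------------------
# Edge weights and the A* heuristic

_LEGAL = {
    ("M", "M"): ("MM", 1),
    ("M", "I"): ("MI", 0),
    ("M", "D"): ("MD", 1),
    ("I", "M"): ("IM", 1),
    ("I", "I"): ("II", 0),
    ("D", "M"): ("DM", 1),
    ("D", "D"): ("DD", 1),
}


def edge_weight(
    model: ProfileHMM,
    from_state: tuple[str, int],
    to_state: tuple[str, int],
    aa: Optional[str] = None,
    variant: str = "modified",
) -> float:
    """Weight in nats of one profile edge.

    Raw: ``log t`` plus the null-normalised match emission when entering a
    match state.  Modified: additionally subtract ``c_j`` from every edge
    entering column ``j``'s match or delete state (edges into inserts are
    unchanged), which is what makes the search weights monotone.
    """
    fs, fj = from_state
    ts, tj = to_state
    key = (fs, ts)
    if key not in _LEGAL:
        raise IllegalTransition(f"{from_state} -> {to_state}")
    tname, delta = _LEGAL[key]
    if tj != fj + delta:
        raise IllegalTransition(f"{from_state} -> {to_state}: bad column step")
    w = float(model.log_trans[tname][fj])
    if ts == "M":
        if aa is None:
            raise ValueError("entering a match state requires an emitted amino acid")
        w += model.emission_logodds(tj, aa)
    if variant == "modified" and ts in ("M", "D"):
        w -= float(model.max_emission_log[tj])
    elif variant not in ("modified", "raw"):
        raise ValueError(f"unknown weight variant {variant!r}")
    return w


def heuristic_table(model: ProfileHMM) -> dict[str, np.ndarray]:
    """Admissible completion estimates ``h`` per (state type, column).

    ``h(v)`` is the modified weight of the best single step from ``v`` into
    the next match state (for the argmax amino acid the emission term cancels
    ``c``, leaving just ``log t``) plus the all-match suffix of best
    transitions to the end of the model; ``h = 0`` at the terminal column.
    Computed once by suffix sums.
    """
    L = model.L
    log_mm = model.log_trans["MM"]
    suffix = np.zeros(L + 2)
    for j in range(L - 1, -1, -1):
        suffix[j] = log_mm[j] + suffix[j + 1]
    hM = np.zeros(L + 1)
    hI = np.zeros(L + 1)
    hD = np.zeros(L + 1)
    for j in range(L + 1):
        if j >= L:
            continue
        hM[j] = suffix[j]
        hI[j] = model.log_trans["IM"][j] + suffix[j + 1]
        hD[j] = model.log_trans["DM"][j] + suffix[j + 1]
    return {"M": hM, "I": hI, "D": hD}


def bit_score(raw_weight_nats: float) -> float:
    """Convert a raw log-odds path score from nats to bits."""
    return raw_weight_nats / LN2


def score_constant(model: ProfileHMM, columns: Iterable[int]) -> float:
    """``sum c_j`` over the given columns: the path-independent offset between
    raw and modified scores of any complete path consuming those columns."""
    c = model.max_emission_log
    return float(sum(c[j] for j in columns))
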