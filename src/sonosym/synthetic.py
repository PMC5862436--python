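"""Synthetic sound-symbolic corpora with planted structure.

The generator emulates the design of the improvised-onomatopoeia study this
package analyses: a cohort of speakers each responds once to every stimulus
in three blocks — audio (3 movements × 2 sound frequencies), video
(2 shapes × 2 sizes × 3 movements) and audiovisual (all four factors) —
producing ``n_speakers × (6 + 12 + 24)`` words.

Words are built from CV skeletons so that every word contains both
consonants and vowels.  The *planted* structure mirrors the effects the
analysis is meant to detect:

* consonant **manner** encodes movement — hits draw plosives, slides draw
  fricatives, rings draw liquids and nasals;
* vowel **backness/roundness** encodes shape in the video block (spiky →
  front unrounded, rounded → back rounded) and sound frequency in the audio
  and audiovisual blocks (high → front unrounded, low → back rounded).

Effect strengths ``beta_manner`` and ``beta_vowel`` interpolate between a
uniform null (0) and the deterministic planted mapping (1).  Speakers get
idiosyncratic log-preference offsets over phoneme classes, drawn once per
speaker with scale ``sigma_speaker``.  The optional audiovisual coupling
rule reproduces the multisensory regime in which movement also biases vowel
choice while the shape effect disappears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import MOVEMENTS, OnomatopoeiaRecord, SHAPES, SIZES, SOUNDS
from .phonology import PhonemeFeatureTable, default_table

MANNERS: tuple[str, ...] = ("plosive", "fricative", "liquid", "nasal")

#: planted manner distribution per movement (rows sum to 1)
MANNER_GIVEN_MOVEMENT: dict[str, tuple[float, float, float, float]] = {
    "hit": (1.0, 0.0, 0.0, 0.0),
    "slide": (0.0, 1.0, 0.0, 0.0),
    "ring": (0.0, 0.0, 0.5, 0.5),
}


def _default_length_probs() -> dict[int, float]:
    return {2: 0.15, 3: 0.35, 4: 0.30, 5: 0.15, 6: 0.05}


def _default_templates() -> dict[int, tuple[str, ...]]:
    return {
        2: ("CV",),
        3: ("CVC",),
        4: ("CVCV",),
        5: ("CVCCV", "CVCVC"),
        6: ("CVCVCV",),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort design, word-shape laws and planted effect strengths."""

    n_speakers: int = 19
    length_probs: Mapping[int, float] = field(default_factory=_default_length_probs)
    templates: Mapping[int, tuple[str, ...]] = field(default_factory=_default_templates)
    beta_manner: float = 0.7
    beta_vowel: float = 0.7
    sigma_speaker: float = 0.5
    av_coupling: bool = True
    av_movement_vowel_weight: float = 0.3
    v_code_permuted: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_speakers < 1:
            raise ValueError("n_speakers must be >= 1")
        total = sum(self.length_probs.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.length_probs.values()):
            raise ValueError(f"length_probs must be a probability law (sum {total})")
        for n in self.length_probs:
            if n not in self.templates:
                raise ValueError(f"no CV template for word length {n}")
            for t in self.templates[n]:
                if len(t) != n or set(t) - {"C", "V"}:
                    raise ValueError(f"bad template {t!r} for length {n}")
        for name in ("beta_manner", "beta_vowel"):
            b = getattr(self, name)
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {b}")
        if self.sigma_speaker < 0:
            raise ValueError("sigma_speaker must be >= 0")
        if not 0.0 <= self.av_movement_vowel_weight <= 1.0:
            raise ValueError("av_movement_vowel_weight must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """The planted conditional phoneme-class distributions.

    ``manner`` rows are indexed by (modality, movement) over the four
    manners; ``vowel`` rows by (modality, condition label) over the vowel
    inventory.  Every row is a probability distribution.
    """

    manner: pd.DataFrame
    vowel: pd.DataFrame


class _Inventory:
    """Manner-grouped consonants and pole-grouped vowels of a feature table."""

    def __init__(self, table: PhonemeFeatureTable):
        from .phonology import IPA_FEATURES

        self.by_manner: dict[str, list[str]] = {m: [] for m in MANNERS}
        self.vowels: list[str] = []
        for sym in table.symbols:
            d = dict(zip(IPA_FEATURES, table.ipa_flags(sym).tolist()))
            if table.is_vowel(sym):
                self.vowels.append(sym)
            else:
                for m in MANNERS:
                    if d[m]:
                        self.by_manner[m].append(sym)
        dv = {
            v: dict(zip(IPA_FEATURES, table.ipa_flags(v).tolist())) for v in self.vowels
        }
        self.front_unrounded = [v for v in self.vowels if not dv[v]["back"] and not dv[v]["round"]]
        self.back_rounded = [v for v in self.vowels if dv[v]["back"] and dv[v]["round"]]
        self.open_vowels = [v for v in self.vowels if dv[v]["open"]]
        self.close_front = [v for v in self.vowels if dv[v]["close"] and not dv[v]["back"]]

    def pole(self, members: Sequence[str]) -> np.ndarray:
        p = np.zeros(len(self.vowels))
        for m in members:
            p[self.vowels.index(m)] = 1.0 / len(members)
        return p


def _mix(uniform: np.ndarray, planted: np.ndarray, beta: float) -> np.ndarray:
    return (1.0 - beta) * uniform + beta * planted


def _tilt(p: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Apply speaker log-preference offsets without leaving the support."""
    w = p * np.exp(offsets)
    return w / w.sum()


def _vowel_pole(inv: _Inventory, level: str) -> np.ndarray:
    """Planted vowel distribution for one shape or sound-frequency level."""
    if level in ("spiky", "HF"):
        return inv.pole(inv.front_unrounded)
    if level in ("rounded", "LF"):
        return inv.pole(inv.back_rounded)
    raise ValueError(f"no vowel pole for level {level!r}")


def _movement_vowel_pole(inv: _Inventory, movement: str) -> np.ndarray:
    # arbitrary but fixed: hits pull open vowels, slides close front
    # vowels, rings back rounded vowels
    if movement == "hit":
        return inv.pole(inv.open_vowels)
    if movement == "slide":
        return inv.pole(inv.close_front)
    return inv.pole(inv.back_rounded)


def _stimulus_grid() -> list[dict]:
    grid: list[dict] = []
    for mov in MOVEMENTS:
        for snd in SOUNDS:
            grid.append({"modality": "A", "movement": mov, "sound": snd})
    for shp in SHAPES:
        for sz in SIZES:
            for mov in MOVEMENTS:
                grid.append({"modality": "V", "movement": mov, "shape": shp, "size": sz})
    for shp in SHAPES:
        for sz in SIZES:
            for mov in MOVEMENTS:
                for snd in SOUNDS:
                    grid.append(
                        {"modality": "AV", "movement": mov, "shape": shp, "size": sz, "sound": snd}
                    )
    return grid


def _vowel_distribution(
    cfg: SyntheticConfig, inv: _Inventory, stim: dict
) -> np.ndarray:
    uniform = np.full(len(inv.vowels), 1.0 / len(inv.vowels))
    modality = stim["modality"]
    if modality == "A":
        planted = _vowel_pole(inv, stim["sound"])
    elif modality == "V":
        planted = _vowel_pole(inv, stim["shape"])
    else:
        if cfg.av_coupling:
            w = cfg.av_movement_vowel_weight
            planted = (1 - w) * _vowel_pole(inv, stim["sound"]) + w * _movement_vowel_pole(
                inv, stim["movement"]
            )
        else:
            planted = 0.5 * _vowel_pole(inv, stim["sound"]) + 0.5 * _vowel_pole(
                inv, stim["shape"]
            )
    return _mix(uniform, planted, cfg.beta_vowel)


#: derangement used when the video block is given an unrelated movement code
_V_PERMUTATION = {"hit": "slide", "slide": "ring", "ring": "hit"}


def _manner_distribution(
    cfg: SyntheticConfig, movement: str, modality: str = "A"
) -> np.ndarray:
    """Manner law for one movement; optionally permuted in the video block.

    With ``v_code_permuted`` the video block maps movements to manners
    through a derangement of the shared code, modelling a modality whose
    sound-symbolic code does not transfer to the others.
    """
    if modality == "V" and cfg.v_code_permuted:
        movement = _V_PERMUTATION[movement]
    uniform = np.full(len(MANNERS), 0.25)
    planted = np.array(MANNER_GIVEN_MOVEMENT[movement])
    return _mix(uniform, planted, cfg.beta_manner)


def _build_word(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    inv: _Inventory,
    p_manner: np.ndarray,
    p_vowel: np.ndarray,
    manner_offsets: np.ndarray,
    vowel_offsets: np.ndarray,
) -> str:
    lengths = sorted(cfg.length_probs)
    probs = np.array([cfg.length_probs[n] for n in lengths])
    n = lengths[rng.choice(len(lengths), p=probs / probs.sum())]
    templates = cfg.templates[n]
    template = templates[rng.integers(len(templates))]
    pm = _tilt(p_manner, manner_offsets)
    pv = _tilt(p_vowel, vowel_offsets)
    word = []
    for slot in template:
        if slot == "C":
            manner = MANNERS[rng.choice(len(MANNERS), p=pm)]
            pool = inv.by_manner[manner]
            word.append(pool[rng.integers(len(pool))])
        else:
            word.append(inv.vowels[rng.choice(len(inv.vowels), p=pv)])
    return "".join(word)


def generate_corpus(
    cfg: SyntheticConfig | None = None,
    table: PhonemeFeatureTable | None = None,
) -> tuple[list[OnomatopoeiaRecord], GroundTruth]:
    """Generate one record per speaker × stimulus, plus the planted truth.

    Fully reproducible from ``cfg.seed``: the same configuration always
    yields byte-identical corpora.
    """
    cfg = cfg or SyntheticConfig()
    cfg.validate()
    table = table or default_table()
    inv = _Inventory(table)
    rng = np.random.default_rng(cfg.seed)

    speakers = [f"s{i + 1:02d}" for i in range(cfg.n_speakers)]
    manner_offsets = {
        s: rng.normal(0.0, cfg.sigma_speaker, len(MANNERS)) for s in speakers
    }
    vowel_offsets = {
        s: rng.normal(0.0, cfg.sigma_speaker, len(inv.vowels)) for s in speakers
    }

    grid = _stimulus_grid()
    records: list[OnomatopoeiaRecord] = []
    for s in speakers:
        for stim in grid:
            word = _build_word(
                rng,
                cfg,
                inv,
                _manner_distribution(cfg, stim["movement"], stim["modality"]),
                _vowel_distribution(cfg, inv, stim),
                manner_offsets[s],
                vowel_offsets[s],
            )
            records.append(
                OnomatopoeiaRecord(
                    speaker=s,
                    modality=stim["modality"],
                    movement=stim["movement"],
                    shape=stim.get("shape"),
                    size=stim.get("size"),
                    sound=stim.get("sound"),
                    ipa=word,
                )
            )

    manner_rows = {
        (mod, mov): _manner_distribution(cfg, mov, mod)
        for mod in ("A", "V", "AV")
        for mov in MOVEMENTS
    }
    vowel_rows = {}
    for stim in grid:
        label_parts = [stim.get("shape"), stim.get("sound"), stim["movement"]]
        label = "/".join(p for p in label_parts if p)
        vowel_rows[(stim["modality"], label)] = _vowel_distribution(cfg, inv, stim)
    truth = GroundTruth(
        manner=pd.DataFrame(
            manner_rows.values(),
            index=pd.MultiIndex.from_tuples(manner_rows, names=["modality", "movement"]),
            columns=list(MANNERS),
        ),
        vowel=pd.DataFrame(
            vowel_rows.values(),
            index=pd.MultiIndex.from_tuples(vowel_rows, names=["modality", "condition"]),
            columns=list(inv.vowels),
        ),
    )
    return records, truth


def expected_separability(cfg: SyntheticConfig) -> dict[str, dict[str, float]]:
    """Qualitative decoding bounds implied by the planted structure.

    With a deterministic movement→manner mapping and no speaker noise the
    classes are linearly separable in manner proportions, so movement
    decoding from consonant features must approach φ = 1; with no planted
    effect φ is consistent with 0.
    """
    cfg.validate()
    out: dict[str, dict[str, float]] = {}
    if cfg.beta_manner == 1.0 and cfg.sigma_speaker == 0.0:
        out["movement_from_consonants"] = {"phi_min": 0.95}
    if cfg.beta_manner == 0.0:
        out["movement_from_consonants"] = {"phi_abs_max": 0.1}
    if cfg.beta_vowel == 0.0:
        out["shape_sound_from_vowels"] = {"phi_abs_max": 0.1}
    return out


# ---------------------------------------------------------------------------
# cross-linguistic word lists with planted movement mixtures


def default_actions() -> dict[str, tuple[float, float, float]]:
    """Planted (hit, slide, ring) mixtures for a set of object actions."""
    return {
        "crash": (1.0, 0.0, 0.0),
        "knock": (1.0, 0.0, 0.0),
        "dull_strike": (1.0, 0.0, 0.0),
        "telephone": (0.0, 0.0, 1.0),
        "doorbell": (0.0, 0.0, 1.0),
        "swish": (0.0, 1.0, 0.0),
        "skid": (0.0, 1.0, 0.0),
        "falling_strike": (0.5, 0.5, 0.0),
        "wet_strike": (1 / 3, 1 / 3, 1 / 3),
    }


def generate_wordlist(
    actions: Mapping[str, tuple[float, float, float]] | None = None,
    n_languages: int = 12,
    n_raters: int = 20,
    rating_noise: float = 8.0,
    form_effect: float = 0.9,
    seed: int = 0,
    table: PhonemeFeatureTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate a cross-linguistic onomatopoeia list plus human ratings.

    For each action, each of ``n_languages`` pseudo-languages contributes a
    form built by drawing a movement from the action's planted mixture and
    sampling a word whose consonant manners follow that movement with
    strength ``form_effect``.  Raters report noisy percentages around the
    planted mixture (clipped at 0, not forced to sum to 100 — the reader
    normalizes).

    Returns ``(wordlist, ratings)``: wordlist with columns
    action/language/form, ratings with columns rater/action/hit/slide/ring.
    """
    actions = actions or default_actions()
    table = table or default_table()
    inv = _Inventory(table)
    rng = np.random.default_rng(seed)
    cfg = SyntheticConfig(beta_manner=form_effect, beta_vowel=0.0, sigma_speaker=0.0)
    uniform_v = np.full(len(inv.vowels), 1.0 / len(inv.vowels))
    no_off_m = np.zeros(len(MANNERS))
    no_off_v = np.zeros(len(inv.vowels))

    wl_rows = []
    for action, mixture in actions.items():
        mix = np.asarray(mixture, dtype=float)
        if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError(f"action {action!r}: mixture must be a distribution")
        for li in range(n_languages):
            movement = MOVEMENTS[rng.choice(3, p=mix)]
            form = _build_word(
                rng, cfg, inv,
                _manner_distribution(cfg, movement), uniform_v,
                no_off_m, no_off_v,
            )
            wl_rows.append({"action": action, "language": f"lang{li + 1:02d}", "form": form})
    wordlist = pd.DataFrame(wl_rows)

    rt_rows = []
    for ri in range(n_raters):
        for action, mixture in actions.items():
            pct = 100.0 * np.asarray(mixture) + rng.normal(0.0, rating_noise, 3)
            pct = np.clip(pct, 0.0, None)
            if pct.sum() == 0:
                pct = np.full(3, 100.0 / 3)
            rt_rows.append(
                {
                    "rater": f"r{ri + 1:02d}",
                    "action": action,
                    "hit": pct[0],
                    "slide": pct[1],
                    "ring": pct[2],
                }
            )
    ratings = pd.DataFrame(rt_rows)
    return wordlist, ratings
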