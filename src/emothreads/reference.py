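"""Published summary statistics for three online discussion communities.

These are the reported corpus-level statistics for the BBC Message Boards
(Religion & Ethics and World/UK News, 2005-2009), a full Digg crawl
(Feb-Apr 2009) and a Blogs06 subset: post counts, pooled valence
frequencies and the fitted preferential exponents per valence class.  They
serve as realistic generator settings and as the nine (p_e, alpha_e)
points for the exponent-versus-frequency fit.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CommunityStats", "BBC", "DIGG", "BLOGS", "COMMUNITIES", "alpha_vs_p_points"]


@dataclass(frozen=True)
class CommunityStats:
    name: str
    n_comments: int
    n_users: int | None
    n_threads: int
    mean_valence: float
    p_plus: float
    p_minus: float
    p_zero: float
    alpha_plus: float
    alpha_minus: float
    alpha_zero: float

    @property
    def p_vec(self) -> tuple[float, float, float]:
        """(p_plus, p_minus, p_zero), the generator marginal order."""
        return (self.p_plus, self.p_minus, self.p_zero)

    @property
    def alpha_vec(self) -> tuple[float, float, float]:
        """(alpha_plus, alpha_minus, alpha_zero)."""
        return (self.alpha_plus, self.alpha_minus, self.alpha_zero)

    @property
    def mean_thread_length(self) -> float:
        return self.n_comments / self.n_threads

    def p(self, valence: int) -> float:
        return {1: self.p_plus, -1: self.p_minus, 0: self.p_zero}[valence]

    def alpha(self, valence: int) -> float:
        return {1: self.alpha_plus, -1: self.alpha_minus, 0: self.alpha_zero}[valence]


BBC = CommunityStats(
    name="BBC",
    n_comments=2_474_781,
    n_users=18_045,
    n_threads=97_946,
    mean_valence=-0.44,
    p_plus=0.19, p_minus=0.65, p_zero=0.16,
    alpha_plus=0.38, alpha_minus=0.05, alpha_zero=0.45,
)

DIGG = CommunityStats(
    name="Digg",
    n_comments=1_646_153,
    n_users=84_985,
    n_threads=129_998,
    mean_valence=-0.16,
    p_plus=0.31, p_minus=0.48, p_zero=0.21,
    alpha_plus=0.20, alpha_minus=0.11, alpha_zero=0.37,
)

BLOGS = CommunityStats(
    name="Blogs",
    n_comments=242_057,
    n_users=None,
    n_threads=1_219,
    mean_valence=0.14,
    p_plus=0.35, p_minus=0.22, p_zero=0.43,
    alpha_plus=0.23, alpha_minus=0.19, alpha_zero=0.16,
)

COMMUNITIES = (BBC, DIGG, BLOGS)


def alpha_vs_p_points() -> list[tuple[float, float]]:
    """The nine (emotion frequency, preferential exponent) pairs, pooled
    over the three communities and three valence classes."""
    return [
        (c.p(e), c.alpha(e)) for c in COMMUNITIES for e in (1, -1, 0)
    ]
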