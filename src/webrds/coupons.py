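"""e-Coupon code space and registry.

Recruitment invitations are single-use 5-character codes drawn from a
case-sensitive alphanumeric alphabet with the eight glyphs that are
easy to misread (0, o, O, i, I, L, l, 1) removed, leaving 54 characters
and a pool of 54**5 = 459,165,024 possible codes.  The registry tracks
each code's full lifecycle — issued, activated, expiring, cancelled,
used — and validates submitted codes against those attributes in a
fixed order, reporting the first failed check.
"""

from __future__ import annotations

import csv
import string
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .clock import DAY, from_iso, to_iso

AMBIGUOUS = "0oOiILl1"
CODE_LENGTH = 5
DEFAULT_EXPIRY = 14 * DAY


class CouponError(Exception):
    """Registry-level failure (capacity exhausted, unknown code, ...)."""


@dataclass(frozen=True)
class CodeAlphabet:
    """Ordered set of characters allowed in coupon codes."""

    characters: str

    def __contains__(self, ch: str) -> bool:
        return ch in self.characters

    def __len__(self) -> int:
        return len(self.characters)


def build_alphabet() -> CodeAlphabet:
    """The 54-character code alphabet: [A-Za-z0-9] minus ambiguous glyphs."""
    chars = [
        c
        for c in string.ascii_uppercase + string.ascii_lowercase + string.digits
        if c not in AMBIGUOUS
    ]
    return CodeAlphabet("".join(chars))


def pool_size(alphabet: CodeAlphabet, length: int) -> int:
    """Exact number of codes of the given length (|alphabet| ** length)."""
    if length < 1:
        raise ValueError(f"code length must be >= 1, got {length}")
    return len(alphabet) ** length


class FailureReason(str, Enum):
    NOT_ISSUED = "not_issued"
    NOT_ACTIVATED = "not_activated"
    EXPIRED = "expired"
    CANCELLED = "cancelled"
    ALREADY_USED = "already_used"


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    failure_reason: Optional[FailureReason] = None

    def __post_init__(self) -> None:
        assert self.valid == (self.failure_reason is None)


@dataclass
class CouponRecord:
    code: str
    issuer: str  # participant id, or "SEED_PORTAL" for staff-issued seed coupons
    activated: bool = True
    activation_date: int = 0
    expiration_date: int = DEFAULT_EXPIRY
    cancelled: bool = False
    used: bool = False
    redeemed_by: Optional[str] = None
    redeemed_at: Optional[int] = None


# CSV column order for registry serialization.
_CSV_FIELDS = [
    "code",
    "issuer",
    "activated",
    "activation_date",
    "expiration_date",
    "cancelled",
    "used",
    "redeemed_by",
    "redeemed_at",
]


@dataclass
class CouponRegistry:
    """All coupons issued in one survey, keyed by code (unique)."""

    alphabet: CodeAlphabet = field(default_factory=build_alphabet)
    code_length: int = CODE_LENGTH
    expiry_interval: int = DEFAULT_EXPIRY
    _by_code: dict[str, CouponRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def get(self, code: str) -> CouponRecord:
        try:
            return self._by_code[code]
        except KeyError:
            raise CouponError(f"code not in registry: {code!r}") from None

    def records(self) -> Iterable[CouponRecord]:
        return self._by_code.values()

    def insert(self, record: CouponRecord) -> None:
        if record.code in self._by_code:
            raise CouponError(f"duplicate code: {record.code!r}")
        if len(record.code) != self.code_length or any(
            c not in self.alphabet for c in record.code
        ):
            raise CouponError(f"code {record.code!r} not over the registry alphabet")
        self._by_code[record.code] = record

    # -- generation ----------------------------------------------------

    def generate(
        self,
        n: int,
        issuer: str,
        now: int = 0,
        rng: np.random.Generator | int | None = None,
        expires: int | None = None,
    ) -> list[CouponRecord]:
        """Generate n fresh, activated codes distinct from all existing ones.

        Reproducible when `rng` is a seeded generator or an integer seed.
        Raises CouponError if the code pool cannot accommodate n more codes.
        """
        if n < 0:
            raise ValueError("n must be >= 0")
        pool = pool_size(self.alphabet, self.code_length)
        if n + len(self._by_code) > pool:
            raise CouponError(
                f"code pool exhausted: {len(self._by_code)} existing + {n} requested "
                f"> pool {pool}"
            )
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        chars = self.alphabet.characters
        exp = now + self.expiry_interval if expires is None else expires
        out: list[CouponRecord] = []
        seen = self._by_code
        while len(out) < n:
            # vectorised draw; rejected collisions are redrawn (birthday-safe)
            need = n - len(out)
            idx = rng.integers(0, len(chars), size=(need, self.code_length))
            for row in idx:
                code = "".join(chars[i] for i in row)
                if code in seen:
                    continue
                rec = CouponRecord(
                    code=code,
                    issuer=issuer,
                    activated=True,
                    activation_date=now,
                    expiration_date=exp,
                )
                self._by_code[code] = rec
                out.append(rec)
                if len(out) == n:
                    break
        return out

    # -- validation ----------------------------------------------------

    def validate(self, code: str, now: int) -> ValidationResult:
        """Check a submitted code: issued, activated, unexpired, not
        cancelled, not already used — in that order; first failure wins."""
        rec = self._by_code.get(code)
        if rec is None:
            return ValidationResult(False, FailureReason.NOT_ISSUED)
        if not rec.activated or now < rec.activation_date:
            return ValidationResult(False, FailureReason.NOT_ACTIVATED)
        if now > rec.expiration_date:
            return ValidationResult(False, FailureReason.EXPIRED)
        if rec.cancelled:
            return ValidationResult(False, FailureReason.CANCELLED)
        if rec.used:
            return ValidationResult(False, FailureReason.ALREADY_USED)
        return ValidationResult(True)

    def redeem(self, code: str, by: str, at: int) -> CouponRecord:
        rec = self.get(code)
        rec.used = True
        rec.redeemed_by = by
        rec.redeemed_at = at
        return rec

    # -- administration ------------------------------------------------

    def cancel(self, codes: Sequence[str]) -> None:
        for code in codes:
            self.get(code).cancelled = True

    def set_activation(self, codes: Sequence[str], date: int) -> None:
        for code in codes:
            rec = self.get(code)
            rec.activated = True
            rec.activation_date = date

    def set_expiration(self, codes: Sequence[str], date: int) -> None:
        for code in codes:
            self.get(code).expiration_date = date

    # -- serialization -------------------------------------------------

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
            w.writeheader()
            for rec in self._by_code.values():
                w.writerow(
                    {
                        "code": rec.code,
                        "issuer": rec.issuer,
                        "activated": str(rec.activated).lower(),
                        "activation_date": to_iso(rec.activation_date),
                        "expiration_date": to_iso(rec.expiration_date),
                        "cancelled": str(rec.cancelled).lower(),
                        "used": str(rec.used).lower(),
                        "redeemed_by": rec.redeemed_by or "",
                        "redeemed_at": to_iso(rec.redeemed_at),
                    }
                )

    @classmethod
    def from_csv(cls, path: str, **kwargs) -> "CouponRegistry":
        reg = cls(**kwargs)
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                reg.insert(
                    CouponRecord(
                        code=row["code"],
                        issuer=row["issuer"],
                        activated=row["activated"] == "true",
                        activation_date=from_iso(row["activation_date"]) or 0,
                        expiration_date=from_iso(row["expiration_date"]) or 0,
                        cancelled=row["cancelled"] == "true",
                        used=row["used"] == "true",
                        redeemed_by=row["redeemed_by"] or None,
                        redeemed_at=from_iso(row["redeemed_at"]),
                    )
                )
        return reg


@dataclass
class CouponPolicy:
    """How many e-coupons a completing recruiter is issued.

    The default applies survey-wide; conditional rules (first match wins)
    let administrators vary issuance by recruiter characteristics, e.g.
    region or age band.  Setting the count to 0 halts sampling: interview
    completions then issue no further coupons.
    """

    coupons_per_recruiter: int = 3
    rules: list[tuple[dict, int]] = field(default_factory=list)

    def coupons_for(self, attributes: dict | None = None) -> int:
        attributes = attributes or {}
        for predicate, count in self.rules:
            if all(attributes.get(k) == v for k, v in predicate.items()):
                return count
        return self.coupons_per_recruiter


def administer(
    registry: CouponRegistry,
    action: str,
    targets: Sequence[str] | None = None,
    value=None,
    policy: CouponPolicy | None = None,
) -> None:
    """Apply one administrative action to the registry or coupon policy.

    Actions: 'cancel', 'set_activation', 'set_expiration' (per-coupon,
    `targets` required) and 'set_coupons_per_recruiter' (policy-level;
    `value` is the new count, optionally conditioned via a (predicate,
    count) tuple).  Per-coupon actions are atomic: all targets are
    checked before any change is applied.
    """
    targets = list(targets or [])
    if action in ("cancel", "set_activation", "set_expiration"):
        for code in targets:  # verify first: atomicity
            registry.get(code)
        if action == "cancel":
            registry.cancel(targets)
        elif action == "set_activation":
            registry.set_activation(targets, int(value))
        else:
            registry.set_expiration(targets, int(value))
    elif action == "set_coupons_per_recruiter":
        if policy is None:
            raise ValueError("policy required for set_coupons_per_recruiter")
        if isinstance(value, tuple):
            predicate, count = value
            policy.rules.insert(0, (dict(predicate), int(count)))
        else:
            policy.coupons_per_recruiter = int(value)
    else:
        raise ValueError(f"unknown administrative action: {action!r}")
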