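"""e-Coupon code space and lifecycle.

Builds the 54-character code alphabet, computes the size of the
5-character code pool, generates a batch of codes, and walks one coupon
through validation, redemption, and administrative cancellation.
"""

from webrds import CouponRegistry, administer, build_alphabet, pool_size

alphabet = build_alphabet()
print(f"alphabet size: {len(alphabet)}")
print(f"5-character code pool: {pool_size(alphabet, 5):,}")
# 54 characters (upper/lower/digits minus the 8 ambiguous glyphs) give
# 54^5 = 459,165,024 possible coupon codes.

registry = CouponRegistry()
coupons = registry.generate(3, issuer="S01", now=0, rng=42)
print("generated codes:", [c.code for c in coupons])

code = coupons[0].code
print("fresh code valid?", registry.validate(code, now=3600).valid)

registry.redeem(code, by="P00001", at=3600)
print("after redemption:", registry.validate(code, now=7200).failure_reason)
# already_used: each code enrolls at most one recruit.

administer(registry, "cancel", targets=[coupons[1].code])
print("after cancellation:", registry.validate(coupons[1].code, now=7200).failure_reason)
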