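"""The deterministic funnel fixture and its tabulations.

Generates the packaged record-level fixture (35 seeds, 6207 issued
e-coupons), replays it through coupon validation, phone deduplication,
screening, the fraud audit, and the quality screens, and prints the
funnel, redemption-delay, and device tables.
"""

from webrds import generate_funnel_fixture, run_pipeline
from webrds.analytics import delays_table, devices_table, funnel_table

log = generate_funnel_fixture()
print(f"fixture: {len(log)} events")

result = run_pipeline(log)

print("\nFunnel (counts and % of 6207 issued coupons):")
print(funnel_table(result).to_string(index=False))
# Of 6207 issued coupons 3000 are redeemed; the funnel narrows through
# phone dedup, screening, consent and interview completion to 2031
# completers, of whom 317 are fraudulent and 99 fail the attention
# filter, leaving 1615 valid records.

print("\nIssuance-to-redemption delay:")
print(delays_table(log).to_string(index=False))

print("\nRedemption devices and mobile browsers:")
print(devices_table(log).to_string(index=False))

fraud_total = sum(1 for r in result.roster.participants.values() if r.fraud)
straight = [p for p, f in result.flags.items() if f.straightlined]
print(f"\nfraud enrollments: {fraud_total} (1 seed + 317 recruits)")
print(f"straightlined records: {straight} -> fraud-flagged:",
      [result.roster.get(p).fraud for p in straight])
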