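# Substrate signatures for PUL classification.
#
# Curated mapping from PUL CAZy-family composition to a predicted substrate.
# Each entry lists the CAZy families that must all be present in a PUL's
# composition (required_families), families that must be absent
# (forbidden_families), and gene roles that must occur among PUL members
# (required_roles, e.g. sulfatase).  Entries are tried in increasing
# priority order; the first match labels the PUL.  This table is data, not
# code: edit or replace it to change the classification.
- label: GH92-GH20-GH2-CE4
  required_families: [GH92, GH20, GH2, CE4]
  priority: 1
- label: GH136+sulfatase
  required_families: [GH136]
  required_roles: [sulfatase]
  priority: 2
- label: fucoidan
  required_families: [GH29, GH95]
  required_roles: [sulfatase]
  priority: 3
- label: sulfated-rhamnoglucan
  required_families: [GH78, GH88]
  required_roles: [sulfatase]
  priority: 4
- label: mannan
  required_families: [GH76, GH92]
  priority: 5
- label: alginate
  required_families: [PL7]
  priority: 6
- label: laminarin
  required_families: [GH16]
  forbidden_families: [PL7]
  priority: 7
- label: alpha-glucan
  required_families: [GH13]
  priority: 8
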