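# Five-node two-route example: a1 links to intermediates b1/b2, which link to
# candidates c1/c2.  Under the count metric the edge weights are w(a1,b1)=10
# and 2 for the other a/b-to-c1 edges.
mode: deterministic
default_year: 2000
entities:
  - {id: a1, type: Chemical, surfaces: [alpha]}
  - {id: b1, type: Gene, surfaces: [beta-one]}
  - {id: b2, type: Gene, surfaces: [beta-two]}
  - {id: c1, type: Disease, surfaces: [gamma-one]}
  - {id: c2, type: Disease, surfaces: [gamma-two]}
pairs:
  - {a: a1, b: b1, count: 10}
  - {a: a1, b: b2, count: 2}
  - {a: b1, b: c1, count: 2}
  - {a: b2, b: c1, count: 2}
  - {a: b1, b: c2, count: 1}
  - {a: b2, b: c2, count: 1}
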