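# Example dialect modelled on ACM-DL-style fielded search.
name: acm-like
and_token: AND
or_token: OR
wildcard: "*"
phrase_delimiters: ['"', '"']
field_tags:
  title: "Title:({term})"
  abstract: "Abstract:({term})"
  keywords: "Keyword:({term})"
additions: []
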