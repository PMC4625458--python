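"""Default English stopword list.

A standard general-English list of function words and near-content-free
adverbs; domain terms are never stopworded. Callers can supply their own
list to ``fit_idf``/``tokenize`` instead.
"""

STOPWORDS: frozenset[str] = frozenset("""
a about above across actually after afterwards again against all almost
alone along already also although always am among amongst an and another
any anyhow anyone anything anyway anywhere are around as at back be became
because become becomes becoming been before beforehand behind being below
beside besides between beyond both bottom but by call can cannot could did
do does doing done down due during each eg either else elsewhere enough etc
even ever every everyone everything everywhere except few for former
formerly from further had has have having he hence her here hereafter
hereby herein hereupon hers herself him himself his how however ie if in
indeed instead into is it its itself just latter latterly least less may
me meanwhile might mine more moreover most mostly much must my myself
namely neither never nevertheless next no nobody none noone nor not
nothing now nowhere of off often on once one only onto or other others
otherwise our ours ourselves out over own per perhaps please quite rather
re really same seem seemed seeming seems several she should since so some
somehow someone something sometime sometimes somewhere still such than
that the their theirs them themselves then thence there thereafter thereby
therefore therein thereupon these they this those though through throughout
thru thus to together too toward towards under until up upon us very via
was we well were what whatever when whence whenever where whereafter
whereas whereby wherein whereupon wherever whether which while whither who
whoever whole whom whose why will with within without would yet you your
yours yourself yourselves
""".split())
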