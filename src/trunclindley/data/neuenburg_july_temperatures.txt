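# Average July temperatures (degrees C), Neuenburg, Switzerland, 1864-1993
# Source: Barakat, Nigm, El-Adll & Yusuf (2014); n = 130
19.0
20.1
18.4
17.4
19.7
21.0
21.4
19.2
19.9
20.4
20.9
17.2
20.2
17.8
18.1
15.6
19.4
21.7
16.2
16.4
19.0
20.6
19.0
20.7
15.8
17.7
16.8
17.1
18.1
18.4
18.7
18.7
18.4
19.2
18.0
18.7
20.7
19.4
19.2
17.4
22.0
21.4
19.3
16.8
18.2
16.2
15.9
22.1
17.5
15.3
16.5
17.4
17.0
18.3
18.3
15.3
18.2
21.5
17.0
21.6
18.2
18.1
17.6
18.2
22.6
19.9
17.1
17.2
17.3
19.4
20.1
20.1
17.0
19.4
17.5
16.8
17.0
19.9
18.2
19.2
18.5
20.8
19.5
21.1
15.8
21.3
21.2
18.8
22.3
18.6
16.8
18.2
17.2
18.4
18.7
21.1
16.3
17.4
18.0
19.5
21.2
16.8
17.4
20.7
18.4
19.8
18.7
20.5
18.3
18.2
18.2
19.2
20.2
18.2
17.4
19.2
16.3
17.4
20.3
23.4
19.2
20.2
19.3
19.0
18.8
20.3
19.7
20.7
19.6
18.1
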