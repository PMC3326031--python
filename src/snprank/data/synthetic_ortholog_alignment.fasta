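>human
CQRIMCRSMYKENRTDSLKSSFTQKKDELPHGSWTSDKQEGNLLTKMQWFFTPWYVACWE
>ortholog1
SFSEKVISEYHLQCITQMQNHGCDKKCWKPYSKDNLNSDEWGSKGGDDS-ALGEYFSRFR
>ortholog2
QCMWLTCERYWDWHVELNQPPKVNKTSMEIIYRLMRCAQEYACWYAHGHFDTPEEVHRAE
>ortholog3
KMDSFGYIQYIQKSGTRALNAYGMKHRWIYWGGREQPEDENECEHINFDFNYMMVDQIDI
>ortholog4
KYTPCPKLWYCLETFAGDVNHVWSKEQEFCLSCFLKPLEEKYGNMTHQPFMHWACMKGCN
>ortholog5
VRLKNEVLRYLHTKQSSFNCKAGYKHLLHHQGCRVHCENEHKLMMADRWFIFGGRLIATR
>ortholog6
CSMTVSQAIYSFPTPSNDCNYFKQKARQQDLRKHAPSHSEPLQLTVQRYFHYYKTHVWVV
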