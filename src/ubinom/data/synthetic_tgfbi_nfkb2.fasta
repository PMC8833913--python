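>TGFBI synthetic stand-in (683 aa) carrying LAPVYQKLLER at 670-680, ub site K676
YEMVWQVKEISSNWMCAMIQAIKYCLHANEGYMLDNGRSQNHLGTCANYCNFDHKCFQYM
SWVHQMQFVSSCRCHVVATAGVKYDTQCDFGWVHNAAFMTRWVHINYQHWHRVSYVTNLC
TAETRGDGCMAYQQGWCMKQCAVIMCSYKCFMNFWHWSVKVWNFSYICYDNNGHRQFLCY
NDCHKAENYNLVARITFAARAQDLMLHGSYMYKHLMNWNVQCRMFMHWDLSEGRFITLDD
FRFMCNFYHGHAVASEDKTQHDCAEEHVYRNHAFTCRGVHIQIYNDNWWGCHSRQWYEEH
LVEEKTDNLTIDTIYHKTTAFNKVWFLLRNYAWFTSENLSDHCVKCWADHGIVHYQVTAK
VEFFMWVWWTCHFCRHLFIIHWEWCKIVCASEKCLAEQHGFATLQRGCFQLERHCVNQGI
MWLVRTQLHSLDWDVNGNYQTEKTAWSSYCMNEHSLRDTQSIQCCMSYRTIVTTRWGCSI
ACIHGIGVWKYGVANNDQWEIMEMMKEDVDCGLVMDLVHVQKQMWNYEFSWTCWTRSDLY
DVSISERNATLEWDGRDMHILVALVHTEFYHLARCHFEIMKTDTYHNAELCFEIQGDSRM
CHQGRFTVETCNSEMWSMRWLVDELYSGWQRTIWTCYQWMAIWMKLMMLLYAHIQLEGED
TRDMTIHCRLAPVYQKLLERHSG
>NFKB2 synthetic stand-in (900 aa) carrying YGCEGPSHGGLPGASSEKGR at 55-74 (K72) and GHTPLDLTCSTKVK at 730-743 (K741)
CMCNHAAYQAKGSYHDNYSCILIFQDRAGETMYNCHLRQWNFYNWQYCMSRYFRYGCEGP
SHGGLPGASSEKGRFMDTSIIQYKEDMCAEINQCQTCRYHFQNSNNDFLVWEDMKFYIQD
TWEGFYDWRWYVEIQFDVMQSDRIGQSGVLRVAFWQWVHEMGGVFKQICVNCVMDQFVQL
NNFKTGWILDTLVTYSRCGSAYSWNVAGDAMMRMICYMVSLYWDNRSTDMMDICATMHQM
VKNIAAWAKEQWYWLDMNYYQWCYRNVEELVQNRHIMNVLRNQANNIHICVQWCMWHRHW
LDSVQSEIYTKAYSCIQTLVTTHKEESVQSEMGERECVINKIAAMYLRYALCVYTTTFKE
TQGGGSSFKMQEEFQENSQEIDRMGSEDRGIYAEITQEGQTNRTAWFLHICNECFSQVRT
CHYAITLFLYGILTNKYSYNAQRANCGHYWYYVTSSHHYQRQYTHQHRYFGTTWDIFTMR
YSVVERCYFYQHVWTDIDRGYHCEQNDQCCDSNKDVEIHQDNGIELGHMLERWAQQAWSA
AVWDWRSFFMILANKDNWDNGYHVQDEGWWGKALEHQCSSNYCIYKMLMICCRGDLMYWD
VKGHWVHQDDDCIHFLWKVGHTDARGYDIDSWCLYGIEQANRYQGCHVLVIGTWEKSWYT
CRSWNDNMRMYCLHINYSQVRSHFTASHWMHAYAAHCRCVWTLHVFCGQSYQYWTRAENV
YWRAQGIDRGHTPLDLTCSTKVKAIQACRAWVSDYQGGINFNGNRSIGMVGETEACLRGM
YATYYDSTAVCKDQMMDWHDVVCWDKQSHVLNEAKEFQTHWRSGDNFMEWLDSRQYWNNW
MNNKFMVQNHWQCGIYMNKSTVDILGVLIHNVIELRMHMGQDFHCIWYFKEGQYGIGKYT
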