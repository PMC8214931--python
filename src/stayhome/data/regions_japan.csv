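prefecture,region
Hokkaido,Hokkaido-Tohoku
Aomori,Hokkaido-Tohoku
Iwate,Hokkaido-Tohoku
Miyagi,Hokkaido-Tohoku
Akita,Hokkaido-Tohoku
Yamagata,Hokkaido-Tohoku
Fukushima,Hokkaido-Tohoku
Ibaraki,Kanto
Tochigi,Kanto
Gunma,Kanto
Saitama,Kanto
Chiba,Kanto
Tokyo,Kanto
Kanagawa,Kanto
Niigata,Chubu
Toyama,Chubu
Ishikawa,Chubu
Fukui,Chubu
Yamanashi,Chubu
Nagano,Chubu
Gifu,Chubu
Shizuoka,Chubu
Aichi,Chubu
Mie,Kinki
Shiga,Kinki
Kyoto,Kinki
Osaka,Kinki
Hyogo,Kinki
Nara,Kinki
Wakayama,Kinki
Tottori,Chugoku
Shimane,Chugoku
Okayama,Chugoku
Hiroshima,Chugoku
Yamaguchi,Chugoku
Tokushima,Shikoku
Kagawa,Shikoku
Ehime,Shikoku
Kochi,Shikoku
Fukuoka,Kyushu-Okinawa
Saga,Kyushu-Okinawa
Nagasaki,Kyushu-Okinawa
Oita,Kyushu-Okinawa
Kumamoto,Kyushu-Okinawa
Miyazaki,Kyushu-Okinawa
Kagoshima,Kyushu-Okinawa
Okinawa,Kyushu-Okinawa
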